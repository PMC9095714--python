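"""Seeded synthetic-data generators for desk-scale experiments.

These generators emit inputs with the statistical structure the rest of the
package assumes about real microbial data: genomes that diverge along a
taxonomy tree (substitution-only evolution, so pairwise identity has an exact
closed form), planted homologous gene families whose within-family identity
exceeds between-family identity, codon-usage-biased coding sequences with
known reading frames, and labeled read sets whose classes are separable by
construction (GC content). Every generator is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .corpus import ChunkRecord, LengthDistribution, chunk_genome
from .seqio import SequenceRecord

BASES = np.array(list("ACGT"))

#: NCBI translation table 11 (bacteria/archaea)
_TABLE = CodonTable.unambiguous_dna_by_id[11]
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

#: approximate bulk amino-acid composition of bacterial proteomes
DEFAULT_AA_FREQUENCIES = {
    "A": 0.095, "C": 0.012, "D": 0.054, "E": 0.061, "F": 0.039,
    "G": 0.078, "H": 0.021, "I": 0.060, "K": 0.053, "L": 0.102,
    "M": 0.024, "N": 0.041, "P": 0.044, "Q": 0.040, "R": 0.055,
    "S": 0.060, "T": 0.051, "V": 0.070, "W": 0.012, "Y": 0.028,
}

#: fraction of an amino acid's usage carried by its preferred codon
DEFAULT_CODON_PREFERENCE = 0.75


def default_codon_usage() -> dict[str, float]:
    """A biased 61-entry sense-codon distribution (joint probabilities).

    Per amino acid, the alphabetically first codon carries
    ``DEFAULT_CODON_PREFERENCE`` of the usage and the rest is spread evenly —
    a stylized but realistically strong codon bias, as seen in highly
    expressed prokaryotic genes. Joint probabilities are the per-amino-acid
    conditionals multiplied by the amino-acid frequencies.
    """
    total_aa = sum(DEFAULT_AA_FREQUENCIES.values())
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(_TABLE.forward_table[codon], []).append(codon)
    usage: dict[str, float] = {}
    for aa, codons in by_aa.items():
        aa_freq = DEFAULT_AA_FREQUENCIES[aa] / total_aa
        if len(codons) == 1:
            usage[codons[0]] = aa_freq
            continue
        rest = (1.0 - DEFAULT_CODON_PREFERENCE) / (len(codons) - 1)
        for i, codon in enumerate(sorted(codons)):
            usage[codon] = aa_freq * (DEFAULT_CODON_PREFERENCE if i == 0 else rest)
    return usage


def validate_codon_usage(usage: dict[str, float]) -> None:
    """Check the table covers sense codons with per-amino-acid normalization."""
    by_aa: dict[str, float] = {}
    for codon, freq in usage.items():
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} must not appear in the usage table")
        if freq < 0:
            raise ValueError("codon frequencies must be non-negative")
        by_aa[_TABLE.forward_table[codon]] = by_aa.get(_TABLE.forward_table[codon], 0.0) + freq
    total = sum(usage.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("joint codon frequencies must sum to 1")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world.

    ``branching`` gives the number of children at each tree depth, so the
    number of leaf genomes is the product of its entries; ``substitution_rate``
    is the expected per-site mismatch fraction introduced along each edge.
    """

    branching: tuple[int, ...] = (4, 3)
    substitution_rate: float = 0.05
    genome_length: int = 12_000
    n_gene_families: int = 20
    family_size: int = 5
    gene_length: int = 300
    family_divergence: float = 0.10
    codon_usage: dict[str, float] = field(default_factory=default_codon_usage)
    seed: int = 0

    #: rank names used for successive tree depths
    RANKS = ("phylum", "class", "order", "family", "genus")

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "family_divergence"):
            rate = getattr(self, name)
            if not 0 <= rate < 0.75:
                raise ValueError(f"{name} must lie in [0, 0.75): beyond that substitutions saturate")
        if self.n_gene_families < 2:
            raise ValueError("need at least two gene families")
        if len(self.branching) > len(self.RANKS):
            raise ValueError(f"tree depth limited to {len(self.RANKS)} ranks")
        validate_codon_usage(self.codon_usage)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=probs))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only evolution with expected mismatch fraction ``rate``.

    Each site is independently resampled uniformly over the four bases with
    probability (4/3) * rate, so the expected observed divergence from the
    input is exactly ``rate``; repeated application composes in closed form
    (see :func:`expected_divergence`).
    """
    if not 0 <= rate < 0.75:
        raise ValueError("rate must lie in [0, 0.75)")
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate * 4.0 / 3.0
    arr[hit] = rng.choice(BASES, size=int(hit.sum()))
    return "".join(arr)


def expected_divergence(rates: Sequence[float]) -> float:
    """Exact expected mismatch fraction between two sequences separated by a
    path of edges with the given per-edge rates."""
    survive = np.prod([1.0 - (4.0 / 3.0) * r for r in rates])
    return float(0.75 * (1.0 - survive))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def simulate_taxonomy_genomes(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[SequenceRecord]:
    """Evolve a root genome along a rooted tree; leaves carry taxonomy maps.

    Each edge applies :func:`mutate` at ``spec.substitution_rate``, so two
    leaves at tree distance d have expected divergence
    ``expected_divergence([rate] * d)``, increasing with tree distance.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    root = random_sequence(spec.genome_length, rng)
    ranks = spec.RANKS[: len(spec.branching)]
    leaves: list[SequenceRecord] = []

    def descend(seq: str, depth: int, lineage: list[str]) -> None:
        if depth == len(spec.branching):
            taxonomy = dict(zip(ranks, lineage))
            leaves.append(
                SequenceRecord(id="genome_" + "_".join(lineage), sequence=seq, taxonomy=taxonomy)
            )
            return
        for child in range(spec.branching[depth]):
            name = f"{ranks[depth][0]}{child + 1}" if not lineage else f"{lineage[-1]}.{ranks[depth][0]}{child + 1}"
            descend(mutate(seq, spec.substitution_rate, rng), depth + 1, lineage + [name])

    descend(root, 0, [])
    return leaves


def plant_gene_families(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> dict[str, list[SequenceRecord]]:
    """Families of homologous genes: an ancestor plus diverged copies.

    Each family descends from an independent ancestor coding sequence
    (codon-usage-biased, ``spec.gene_length // 3`` codons) so the genes carry
    the periodic structure real orthologs have; members are copies mutated at
    ``spec.family_divergence`` (substitutions may occasionally disrupt a
    codon, as in genuinely diverged sequences). Within a family the expected
    identity is ``1 - expected_divergence([d, d])`` (members share the
    ancestor), while between families it is near the random baseline 0.25.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    families: dict[str, list[SequenceRecord]] = {}
    for f in range(spec.n_gene_families):
        ancestor = simulate_cds(
            spec.codon_usage, max(20, spec.gene_length // 3), rng, record_id=f"anc{f}"
        )[0].sequence
        gid = f"OG{f:04d}"
        families[gid] = [
            SequenceRecord(
                id=f"{gid}_m{m}",
                sequence=mutate(ancestor, spec.family_divergence, rng),
                label=gid,
            )
            for m in range(spec.family_size)
        ]
    return families


def simulate_cds(
    codon_usage: dict[str, float] | None = None,
    n_codons: int = 100,
    rng: np.random.Generator | None = None,
    record_id: str = "cds",
) -> tuple[SequenceRecord, str]:
    """A coding sequence of ``n_codons`` sense codons drawn i.i.d. from the
    usage table, terminated by a stop codon; returns (record, peptide)."""
    if n_codons < 20:
        raise ValueError("n_codons must be at least 20")
    if codon_usage is None:
        codon_usage = default_codon_usage()
    validate_codon_usage(codon_usage)
    if rng is None:
        rng = np.random.default_rng()
    codons = list(codon_usage)
    probs = np.array([codon_usage[c] for c in codons])
    probs = probs / probs.sum()
    drawn = rng.choice(len(codons), size=n_codons, p=probs)
    seq = "".join(codons[i] for i in drawn) + STOP_CODONS[0]
    peptide = str(Seq(seq).translate(table=11))[:-1]  # strip the stop symbol
    return SequenceRecord(id=record_id, sequence=seq), peptide


@dataclass
class BenchmarkSuite:
    """All desk-scale fixtures, generated from one seed."""

    lm_corpus: list[ChunkRecord]
    genomes: list[SequenceRecord]
    families: dict[str, list[SequenceRecord]]
    frame_chunks: list[ChunkRecord]
    frame_histogram: dict[int, int]
    gc_reads: list[tuple[str, str]]
    seed: int


#: GC contents of the three separable read classes (stand-ins for habitat- or
#: temperature-linked composition classes); pairwise gaps are >= 10 points
GC_CLASSES = {"low_gc": 0.35, "mid_gc": 0.50, "high_gc": 0.65}


def make_benchmark_suite(
    seed: int,
    n_cds: int = 250,
    cds_codons: int = 200,
    reads_per_gc_class: int = 150,
) -> BenchmarkSuite:
    """One call emits every synthetic fixture used by the evaluation suites.

    The language-model corpus comes from chunking the taxonomy-tree genomes;
    the frame dataset from zero-overlap chunking of codon-biased coding
    sequences (sized so each of the six classes has well over 100 examples at
    the defaults); the 3-class read set from GC-content classes separated by
    at least 10 percentage points.
    """
    from .tasks import make_frame_dataset  # local import avoids a cycle

    spec = SyntheticSpec(seed=seed)
    rng = np.random.default_rng(seed)
    genomes = simulate_taxonomy_genomes(spec, np.random.default_rng(rng.integers(2**31)))
    dist = LengthDistribution.default()
    corpus_rng = np.random.default_rng(rng.integers(2**31))
    lm_corpus: list[ChunkRecord] = []
    for g in genomes:
        lm_corpus.extend(chunk_genome(g, dist, corpus_rng))
    families = plant_gene_families(spec, np.random.default_rng(rng.integers(2**31)))
    cds_rng = np.random.default_rng(rng.integers(2**31))
    cds_records = [
        simulate_cds(spec.codon_usage, cds_codons, cds_rng, record_id=f"cds{i:04d}")[0]
        for i in range(n_cds)
    ]
    frame_chunks, frame_histogram = make_frame_dataset(
        cds_records, dist, np.random.default_rng(rng.integers(2**31))
    )
    gc_rng = np.random.default_rng(rng.integers(2**31))
    gc_reads: list[tuple[str, str]] = []
    for label, gc in GC_CLASSES.items():
        for i in range(reads_per_gc_class):
            length = int(gc_rng.choice(dist.support, p=dist.weights))
            gc_reads.append((random_sequence(length, gc_rng, gc=gc), label))
    return BenchmarkSuite(
        lm_corpus=lm_corpus,
        genomes=genomes,
        families=families,
        frame_chunks=frame_chunks,
        frame_histogram=frame_histogram,
        gc_reads=gc_reads,
        seed=seed,
    )
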