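"""Construction of read-length chunk datasets from genomes and coding sequences.

Genomes are cut into non-overlapping fragments whose lengths are drawn from a
read-length distribution bounded to [60, 300] bp (emulating short-read
sequencing output, mean read length 136 bp), each fragment independently
reverse-complemented with probability 0.5. Train/validation/test splits are
made leakage-aware: either along taxonomic branches or so that whole sequence
clusters land in a single partition. Label balancing resamples every class to
the mean per-class count, and a k-mer-screen redundancy filter removes
candidate reads too similar (>80% identity by default) to a reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import SequenceRecord, reverse_complement

MIN_READ_LEN = 60
MAX_READ_LEN = 300
DEFAULT_MEAN_READ_LEN = 136.0
DEFAULT_SD_READ_LEN = 40.0


@dataclass
class LengthDistribution:
    """Discrete distribution over read lengths, supported on [60, 300] bp."""

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.support.size == 0:
            raise ValueError("empty length-distribution support")
        if self.support.size != self.weights.size:
            raise ValueError("support and weights must have equal length")
        if (self.support < MIN_READ_LEN).any() or (self.support > MAX_READ_LEN).any():
            raise ValueError(f"support values must lie in [{MIN_READ_LEN}, {MAX_READ_LEN}]")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def min_length(self) -> int:
        return int(self.support.min())

    def mean(self) -> float:
        return float(np.dot(self.support, self.weights))

    def restricted(self, max_length: int) -> "LengthDistribution | None":
        """The distribution conditioned on lengths <= ``max_length``, or None."""
        mask = self.support <= max_length
        if not mask.any():
            return None
        w = self.weights[mask]
        return LengthDistribution(self.support[mask], w / w.sum())

    @classmethod
    def default(cls) -> "LengthDistribution":
        """Discretized truncated normal, mean 136 bp, sd 40 bp, on [60, 300]."""
        lengths = np.arange(MIN_READ_LEN, MAX_READ_LEN + 1)
        a = (MIN_READ_LEN - DEFAULT_MEAN_READ_LEN) / DEFAULT_SD_READ_LEN
        b = (MAX_READ_LEN - DEFAULT_MEAN_READ_LEN) / DEFAULT_SD_READ_LEN
        pdf = stats.truncnorm.pdf(lengths, a, b, loc=DEFAULT_MEAN_READ_LEN, scale=DEFAULT_SD_READ_LEN)
        return cls(lengths, pdf / pdf.sum())

    @classmethod
    def degenerate(cls, length: int) -> "LengthDistribution":
        return cls(np.array([length]), np.array([1.0]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LengthDistribution":
        """Load an empirical distribution from a two-column TSV (length, weight)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["length", "weight"], comment="#")
        w = df["weight"].to_numpy(float)
        return cls(df["length"].to_numpy(int), w / w.sum())


@dataclass
class ChunkRecord:
    """A read-length fragment with provenance back to its source sequence.

    ``start``/``end`` are 0-based half-open coordinates on the source; strand
    '-' means ``sequence`` is the reverse complement of the source slice.
    """

    chunk_id: str
    source_id: str
    start: int
    end: int
    strand: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError("end - start must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SplitSpec:
    """Assignment of taxa at one rank to train/validation/test partitions."""

    rank: str
    assignment: dict[str, str]

    PARTITIONS = ("train", "validation", "test")

    def __post_init__(self) -> None:
        for taxon, part in self.assignment.items():
            if part not in self.PARTITIONS:
                raise ValueError(f"taxon {taxon!r} assigned to unknown partition {part!r}")


def sample_read_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    """Draw one read length (with replacement) from the distribution."""
    if dist.support.size == 0:  # pragma: no cover - LengthDistribution forbids this
        raise ValueError("empty length-distribution support")
    return int(rng.choice(dist.support, p=dist.weights))


def _make_chunk(
    record: SequenceRecord,
    start: int,
    length: int,
    minus: bool,
    index: int,
) -> ChunkRecord:
    raw = record.sequence[start : start + length]
    strand = "-" if minus else "+"
    seq = reverse_complement(raw) if minus else raw
    return ChunkRecord(
        chunk_id=f"{record.id}|{index}|{start}:{start + length}{strand}",
        source_id=record.id,
        start=start,
        end=start + length,
        strand=strand,
        sequence=seq,
        label=record.label,
    )


def chunk_genome(
    record: SequenceRecord,
    dist: LengthDistribution | None = None,
    rng: np.random.Generator | None = None,
    revcomp_prob: float = 0.5,
) -> list[ChunkRecord]:
    """Cut a genome (or contig) into zero-overlap read-length chunks.

    Chunks tile the sequence left to right starting at position 0; each chunk's
    length is drawn independently from ``dist`` and each chunk is independently
    reverse-complemented with probability ``revcomp_prob``. Per chunk the
    generator is consumed in a documented order — length draw first, then
    strand draw — so corpora are bit-reproducible from a seed. When the
    remaining suffix no longer accommodates the drawn support, the draw is
    restricted to lengths that still fit; a trailing remainder shorter than the
    minimum support is discarded.
    """
    if dist is None:
        dist = LengthDistribution.default()
    if rng is None:
        rng = np.random.default_rng()
    chunks: list[ChunkRecord] = []
    pos, n = 0, len(record.sequence)
    while n - pos >= dist.min_length:
        remaining = n - pos
        d = dist if remaining >= int(dist.support.max()) else dist.restricted(remaining)
        length = sample_read_length(d, rng)
        minus = bool(rng.random() < revcomp_prob)
        chunks.append(_make_chunk(record, pos, length, minus, len(chunks)))
        pos += length
    return chunks


def chunk_cds_random(
    record: SequenceRecord,
    dist: LengthDistribution | None = None,
    n_chunks: int = 50,
    rng: np.random.Generator | None = None,
    revcomp_prob: float = 0.5,
) -> list[ChunkRecord]:
    """Sample ``n_chunks`` read-length chunks from a CDS at random start positions.

    Overlap between chunks is permitted. Each chunk's length is drawn from
    ``dist``; a draw longer than the record is redrawn from the lengths that
    fit. Each chunk is reverse-complemented with probability ``revcomp_prob``.
    The default of 50 chunks per coding sequence matches the construction of
    read-level gene datasets from CDS collections.
    """
    if dist is None:
        dist = LengthDistribution.default()
    if rng is None:
        rng = np.random.default_rng()
    n = len(record.sequence)
    fitting = dist.restricted(n)
    if fitting is None:
        raise ValueError(
            f"record {record.id!r} ({n} nt) is shorter than every support length"
        )
    chunks = []
    for _ in range(n_chunks):
        length = sample_read_length(dist, rng)
        if length > n:
            length = sample_read_length(fitting, rng)
        start = int(rng.integers(0, n - length + 1))
        minus = bool(rng.random() < revcomp_prob)
        chunks.append(_make_chunk(record, start, length, minus, len(chunks)))
    return chunks


def taxonomic_split(
    records: Sequence[SequenceRecord], spec: SplitSpec
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord], list[SequenceRecord]]:
    """Partition records along taxonomic branches at ``spec.rank``.

    Returns (train, validation, test, unassigned); records whose taxon is not
    in the assignment are reported in the fourth list, never silently dropped.
    Keeping whole taxa inside one partition prevents near-duplicate sequences
    from leaking across train and evaluation sets.
    """
    missing = [
        r.id for r in records if r.taxonomy is None or spec.rank not in r.taxonomy
    ]
    if missing:
        raise ValueError(
            f"records missing rank {spec.rank!r}: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    parts: dict[str, list[SequenceRecord]] = {p: [] for p in SplitSpec.PARTITIONS}
    unassigned: list[SequenceRecord] = []
    for r in records:
        taxon = r.taxonomy[spec.rank]
        if taxon in spec.assignment:
            parts[spec.assignment[taxon]].append(r)
        else:
            unassigned.append(r)
    return parts["train"], parts["validation"], parts["test"], unassigned


def cluster_disjoint_split(
    records: Sequence,
    cluster_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng: np.random.Generator | None = None,
) -> tuple[list, list, list]:
    """Split records so every cluster lies wholly inside one partition.

    Clusters (e.g., groups of sequences above 50% identity) are shuffled, then
    greedily assigned to whichever partition is currently most underfilled
    relative to its target record count. Guarantees no cluster spans two
    partitions, which keeps evaluation sequences dissimilar from training ones.
    """
    if len(records) != len(cluster_ids):
        raise ValueError("records and cluster_ids must have equal length")
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if rng is None:
        rng = np.random.default_rng()
    by_cluster: dict[str, list] = {}
    for rec, cid in zip(records, cluster_ids):
        by_cluster.setdefault(cid, []).append(rec)
    clusters = sorted(by_cluster)
    if len(clusters) < 3:
        raise ValueError("need at least as many clusters as partitions (3)")
    order = rng.permutation(len(clusters))
    total = len(records)
    counts = [0, 0, 0]
    parts: tuple[list, list, list] = ([], [], [])
    for idx in order:
        members = by_cluster[clusters[idx]]
        deficits = [fractions[p] * total - counts[p] for p in range(3)]
        p = int(np.argmax(deficits))
        parts[p].extend(members)
        counts[p] += len(members)
    return parts


def balance_labels(
    dataset: Sequence,
    rng: np.random.Generator | None = None,
    target: int | None = None,
) -> list:
    """Resample a labeled dataset so every label has exactly ``target`` records.

    Default target is the floor of the mean per-label count. Overrepresented
    labels are downsampled without replacement; underrepresented labels are
    oversampled by resampling existing records with replacement.
    """
    if len(dataset) == 0:
        raise ValueError("cannot balance an empty dataset")
    if rng is None:
        rng = np.random.default_rng()
    by_label: dict[str, list] = {}
    for rec in dataset:
        if rec.label is None:
            raise ValueError("every record must carry a label")
        by_label.setdefault(rec.label, []).append(rec)
    if target is None:
        target = int(np.floor(np.mean([len(v) for v in by_label.values()])))
    if target <= 0:
        raise ValueError("balancing target must be positive")
    out: list = []
    for label in sorted(by_label):
        members = by_label[label]
        if len(members) >= target:
            idx = rng.choice(len(members), size=target, replace=False)
        else:
            idx = np.concatenate(
                [np.arange(len(members)), rng.choice(len(members), size=target - len(members), replace=True)]
            )
        out.extend(members[i] for i in idx)
    return out


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i)
    return pos


def _best_identity(candidate: str, reference: str, k: int) -> float:
    """Best gapless identity of candidate against reference.

    Shared k-mers propose diagonals (candidate offset minus reference offset);
    on each diagonal the identity is matched positions divided by candidate
    length. Returns 0.0 when no k-mer is shared.
    """
    ref_pos = _kmer_positions(reference, k)
    diagonals: set[int] = set()
    for i in range(len(candidate) - k + 1):
        kmer = candidate[i : i + k]
        for j in ref_pos.get(kmer, ()):
            diagonals.add(i - j)
    best = 0.0
    for diag in diagonals:
        # candidate[i] aligns with reference[i - diag]
        lo = max(0, diag)
        hi = min(len(candidate), len(reference) + diag)
        if hi <= lo:
            continue
        matches = sum(
            1 for i in range(lo, hi) if candidate[i] == reference[i - diag]
        )
        best = max(best, matches / len(candidate))
    return best


def redundancy_filter(
    candidates: Sequence,
    reference: Sequence,
    identity_threshold: float = 0.8,
    k: int = 11,
) -> list:
    """Drop candidates whose identity to any reference read exceeds the threshold.

    A fast stand-in for greedy identity clustering at the 80% cutoff: an exact
    shared k-mer screen (k=11) proposes gapless diagonals, and the best
    diagonal identity (matches / candidate length) decides removal. Candidates
    sharing no 11-mer with any reference read are always retained. Records may
    be ChunkRecords or any object with a ``sequence`` attribute; plain strings
    are accepted too.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must lie in (0, 1]")

    def seq_of(r):
        return r if isinstance(r, str) else r.sequence

    ref_seqs = [seq_of(r).upper() for r in reference]
    kept = []
    for cand in candidates:
        cseq = seq_of(cand).upper()
        if all(_best_identity(cseq, rseq, k) <= identity_threshold for rseq in ref_seqs):
            kept.append(cand)
    return kept


CHUNK_COLUMNS = ["chunk_id", "source_id", "start", "end", "strand", "length", "label", "sequence"]


def write_chunks_tsv(chunks: Iterable[ChunkRecord], path: str | Path) -> None:
    rows = [
        (c.chunk_id, c.source_id, c.start, c.end, c.strand, len(c), c.label or "", c.sequence)
        for c in chunks
    ]
    pd.DataFrame(rows, columns=CHUNK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_chunks_tsv(path: str | Path) -> list[ChunkRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str}, keep_default_na=False)
    return [
        ChunkRecord(
            chunk_id=row.chunk_id,
            source_id=row.source_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            sequence=row.sequence,
            label=row.label or None,
        )
        for row in df.itertuples()
    ]
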