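"""Chunk-dataset construction: sampling, tiling, splits, balancing, filtering."""

import numpy as np
import pytest

from readlm.corpus import (
    LengthDistribution,
    SplitSpec,
    balance_labels,
    chunk_cds_random,
    chunk_genome,
    cluster_disjoint_split,
    read_chunks_tsv,
    redundancy_filter,
    sample_read_length,
    taxonomic_split,
    write_chunks_tsv,
)
from readlm.seqio import SequenceRecord, reverse_complement


def _random_record(n, seed=0, rec_id="g"):
    rng = np.random.default_rng(seed)
    return SequenceRecord(id=rec_id, sequence="".join(rng.choice(list("ACGT"), size=n)))


class TestLengthDistribution:
    def test_default_bounds_and_mean(self):
        dist = LengthDistribution.default()
        assert dist.support.min() == 60 and dist.support.max() == 300
        assert abs(dist.mean() - 136) < 5  # discretized truncated normal, mean 136

    def test_support_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            LengthDistribution(np.array([59]), np.array([1.0]))
        with pytest.raises(ValueError):
            LengthDistribution(np.array([301]), np.array([1.0]))

    def test_weights_must_normalize(self):
        with pytest.raises(ValueError):
            LengthDistribution(np.array([100, 200]), np.array([0.6, 0.6]))

    def test_from_tsv(self, tmp_path):
        path = tmp_path / "dist.tsv"
        path.write_text("100\t2\n200\t2\n")
        dist = LengthDistribution.from_tsv(path)
        assert list(dist.support) == [100, 200]
        assert np.allclose(dist.weights, [0.5, 0.5])


class TestSampleReadLength:
    def test_degenerate_always_returns_its_length(self):
        dist = LengthDistribution.degenerate(100)
        rng = np.random.default_rng(0)
        assert all(sample_read_length(dist, rng) == 100 for _ in range(50))

    def test_two_point_mean_within_monte_carlo_error(self):
        # E = 180, sd per draw = 120 -> se over 10k draws = 1.2
        dist = LengthDistribution(np.array([60, 300]), np.array([0.5, 0.5]))
        rng = np.random.default_rng(1)
        draws = [sample_read_length(dist, rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - 180) < 3 * 1.2

    def test_default_draws_always_in_bounds(self):
        dist = LengthDistribution.default()
        rng = np.random.default_rng(2)
        draws = [sample_read_length(dist, rng) for _ in range(2000)]
        assert min(draws) >= 60 and max(draws) <= 300


class TestChunkGenome:
    def test_too_short_genome_gives_empty_list(self):
        rec = _random_record(59)
        assert chunk_genome(rec, LengthDistribution.default(), np.random.default_rng(0)) == []

    def test_degenerate_tiling_reconstructs_genome(self):
        rec = _random_record(1000)
        chunks = chunk_genome(rec, LengthDistribution.degenerate(100),
                              np.random.default_rng(0), revcomp_prob=0.0)
        assert [c.start for c in chunks] == list(range(0, 1000, 100))
        assert "".join(c.sequence for c in chunks) == rec.sequence

    def test_tiling_is_zero_overlap_prefix(self):
        rec = _random_record(5000, seed=3)
        chunks = chunk_genome(rec, rng=np.random.default_rng(4))
        pos = 0
        for c in chunks:
            assert c.start == pos
            pos = c.end
            assert 60 <= len(c) <= 300
        assert len(rec.sequence) - pos < 300  # only a sub-minimum tail may remain

    def test_minus_strand_sequence_is_reverse_complement_of_slice(self):
        rec = _random_record(4000, seed=5)
        chunks = chunk_genome(rec, rng=np.random.default_rng(6))
        minus = [c for c in chunks if c.strand == "-"]
        assert minus, "expected some minus-strand chunks at 50% strand rate"
        for c in minus[:10]:
            assert c.sequence == reverse_complement(rec.sequence[c.start : c.end])

    def test_same_seed_reproduces_chunks(self):
        rec = _random_record(3000, seed=7)
        a = chunk_genome(rec, rng=np.random.default_rng(42))
        b = chunk_genome(rec, rng=np.random.default_rng(42))
        assert [(c.start, c.end, c.strand) for c in a] == [(c.start, c.end, c.strand) for c in b]


class TestChunkCdsRandom:
    def test_zero_chunks(self):
        rec = _random_record(150)
        assert chunk_cds_random(rec, LengthDistribution.degenerate(100), 0,
                                np.random.default_rng(0)) == []

    def test_starts_within_valid_range(self):
        rec = _random_record(150)
        chunks = chunk_cds_random(rec, LengthDistribution.degenerate(100), 5,
                                  np.random.default_rng(1))
        assert len(chunks) == 5
        assert all(0 <= c.start <= 50 for c in chunks)

    def test_default_draws_50_chunks(self):
        rec = _random_record(400)
        chunks = chunk_cds_random(rec, rng=np.random.default_rng(2))
        assert len(chunks) == 50

    def test_record_shorter_than_support_is_error(self):
        rec = _random_record(80)
        with pytest.raises(ValueError):
            chunk_cds_random(rec, LengthDistribution.degenerate(100), 5,
                             np.random.default_rng(0))


class TestTaxonomicSplit:
    def _records(self, taxa):
        return [
            SequenceRecord(id=f"r{i}", sequence="ACGT" * 20, taxonomy={"class": t})
            for i, t in enumerate(taxa)
        ]

    def test_single_taxon_all_train(self):
        recs = self._records(["a"] * 5)
        spec = SplitSpec(rank="class", assignment={"a": "train"})
        train, valid, test, unassigned = taxonomic_split(recs, spec)
        assert len(train) == 5 and not valid and not test and not unassigned

    def test_partitions_are_disjoint(self):
        recs = self._records(["a", "b", "a", "b", "a"])
        spec = SplitSpec(rank="class", assignment={"a": "train", "b": "test"})
        train, valid, test, _ = taxonomic_split(recs, spec)
        assert {r.id for r in train}.isdisjoint({r.id for r in test})
        assert len(train) == 3 and len(test) == 2

    def test_six_taxon_counts_match_exactly(self):
        taxa = ["a"] * 3 + ["b"] * 2 + ["c"] * 4 + ["d"] * 1 + ["e"] * 5 + ["f"] * 2
        recs = self._records(taxa)
        spec = SplitSpec(
            rank="class",
            assignment={"a": "train", "b": "train", "c": "validation",
                        "d": "validation", "e": "test", "f": "test"},
        )
        train, valid, test, unassigned = taxonomic_split(recs, spec)
        assert (len(train), len(valid), len(test), len(unassigned)) == (5, 5, 7, 0)

    def test_unassigned_taxa_reported_not_dropped(self):
        recs = self._records(["a", "z"])
        spec = SplitSpec(rank="class", assignment={"a": "train"})
        train, _, _, unassigned = taxonomic_split(recs, spec)
        assert len(train) == 1 and len(unassigned) == 1

    def test_missing_rank_is_error_listing_offenders(self):
        recs = self._records(["a"]) + [SequenceRecord(id="bad", sequence="ACGT")]
        spec = SplitSpec(rank="class", assignment={"a": "train"})
        with pytest.raises(ValueError, match="bad"):
            taxonomic_split(recs, spec)


class TestClusterDisjointSplit:
    def test_three_singletons_one_each(self):
        recs = ["r0", "r1", "r2"]
        parts = cluster_disjoint_split(recs, ["c0", "c1", "c2"], (1 / 3, 1 / 3, 1 / 3),
                                       np.random.default_rng(0))
        assert sorted(len(p) for p in parts) == [1, 1, 1]

    def test_no_cluster_spans_partitions(self):
        rng = np.random.default_rng(1)
        cluster_ids = [f"c{i % 10}" for i in range(100)]
        parts = cluster_disjoint_split(list(range(100)), cluster_ids, rng=rng)
        assign = {}
        for pi, part in enumerate(parts):
            for rec in part:
                cid = cluster_ids[rec]
                assert assign.setdefault(cid, pi) == pi

    def test_greedy_fill_matches_targets_within_one_cluster(self):
        records = list(range(1000))
        cluster_ids = [f"c{i // 10}" for i in records]  # 100 clusters of size 10
        parts = cluster_disjoint_split(records, cluster_ids, (0.8, 0.1, 0.1),
                                       np.random.default_rng(2))
        sizes = [len(p) for p in parts]
        assert sum(sizes) == 1000
        for size, frac in zip(sizes, (0.8, 0.1, 0.1)):
            assert abs(size - frac * 1000) <= 10  # within one cluster of target

    def test_fewer_clusters_than_partitions_is_error(self):
        with pytest.raises(ValueError):
            cluster_disjoint_split(["a", "b"], ["c0", "c0"], rng=np.random.default_rng(0))


class _Labeled:
    def __init__(self, name, label):
        self.name, self.label = name, label

    def __repr__(self):
        return f"_Labeled({self.name})"


class TestBalanceLabels:
    def test_mean_rule_counts(self):
        data = [_Labeled(f"a{i}", "A") for i in range(4)] + [_Labeled(f"b{i}", "B") for i in range(2)]
        out = balance_labels(data, np.random.default_rng(0))
        counts = {}
        for rec in out:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        assert counts == {"A": 3, "B": 3}

    def test_balanced_input_is_fixed_point_up_to_order(self):
        data = [_Labeled(f"a{i}", "A") for i in range(3)] + [_Labeled(f"b{i}", "B") for i in range(3)]
        out = balance_labels(data, np.random.default_rng(1))
        assert sorted(r.name for r in out) == sorted(r.name for r in data)

    def test_oversampled_records_come_from_original(self):
        data = [_Labeled(f"a{i}", "A") for i in range(6)] + [_Labeled("b0", "B")]
        out = balance_labels(data, np.random.default_rng(2))
        originals = set(id(r) for r in data)
        assert all(id(r) in originals for r in out)

    def test_empty_dataset_is_error(self):
        with pytest.raises(ValueError):
            balance_labels([], np.random.default_rng(0))


def _identity_oracle(a, b):
    """Best gapless identity over all offsets (brute force)."""
    best = 0.0
    for diag in range(-len(b) + 1, len(a)):
        lo, hi = max(0, diag), min(len(a), len(b) + diag)
        if hi <= lo:
            continue
        matches = sum(a[i] == b[i - diag] for i in range(lo, hi))
        best = max(best, matches / len(a))
    return best


class TestRedundancyFilter:
    def test_identical_candidate_removed(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert redundancy_filter([seq], [seq], 0.8) == []

    def test_empty_reference_keeps_all(self):
        cands = ["ACGTACGTACGTACGT", "TTTTGGGGCCCCAAAA"]
        assert redundancy_filter(cands, [], 0.8) == cands

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            redundancy_filter(["ACGT" * 5], ["ACGT" * 5], 0.0)

    def test_agrees_with_bruteforce_oracle_away_from_margin(self):
        rng = np.random.default_rng(3)
        bases = list("ACGT")
        refs = ["".join(rng.choice(bases, size=60)) for _ in range(20)]
        cands = []
        for i in range(20):
            if i % 2 == 0:
                # high-identity mutants of a reference (few substitutions)
                src = list(refs[i])
                for pos in rng.choice(60, size=3, replace=False):
                    src[pos] = rng.choice(bases)
                cands.append("".join(src))
            else:
                cands.append("".join(rng.choice(bases, size=60)))
        threshold = 0.8
        kept = redundancy_filter(cands, refs, threshold)
        for cand in cands:
            oracle_best = max(_identity_oracle(cand, r) for r in refs)
            if abs(oracle_best - threshold) < 0.05:
                continue  # decisions at the margin are not asserted
            assert (cand in kept) == (oracle_best <= threshold)


def test_chunks_tsv_round_trip(tmp_path):
    rec = _random_record(1000, seed=9)
    chunks = chunk_genome(rec, rng=np.random.default_rng(10))
    for c in chunks[:3]:
        c.label = "frame1"
    path = tmp_path / "chunks.tsv"
    write_chunks_tsv(chunks, path)
    back = read_chunks_tsv(path)
    assert [(c.chunk_id, c.start, c.end, c.strand, c.sequence, c.label) for c in back] == [
        (c.chunk_id, c.start, c.end, c.strand, c.sequence, c.label) for c in chunks
    ]
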