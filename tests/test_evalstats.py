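"""Confusion metrics, homolog pairs, alignment scores, sweeps, correlation, MANOVA."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from readlm.evalstats import (
    AlignmentParams,
    ConfusionMatrix,
    PairRecord,
    build_og_pairs,
    confusion_and_metrics,
    manova_pillai,
    metrics_from_confusion,
    multiclass_confusion,
    pearson_r2,
    read_pairs_tsv,
    smith_waterman_score,
    threshold_sweep,
    write_pairs_tsv,
)


class TestConfusionMetrics:
    def test_all_correct_gives_ones(self):
        _, m = confusion_and_metrics([1, 0, 1], [1, 0, 1], positive_label=1)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_counts(self):
        # TP=3 FP=1 TN=4 FN=2 -> acc .7, prec .75, rec .6, F1 2/3
        truth = [1] * 5 + [0] * 5
        preds = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        cm, m = confusion_and_metrics(truth, preds, positive_label=1)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 1, 4, 2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3)

    def test_zero_denominators_flagged(self):
        _, m = confusion_and_metrics([0, 0], [0, 0], positive_label=1)
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert set(m.undefined) == {"precision", "recall", "f1"}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([1], [1, 0], positive_label=1)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            truth = rng.integers(0, 2, size=30)
            preds = rng.integers(0, 2, size=30)
            _, m = confusion_and_metrics(list(truth), list(preds), positive_label=1)
            if "f1" in m.undefined:
                continue
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_uniform_random_multiclass_accuracy_near_chance(self):
        # a uniform random classifier over k classes converges to 1/k accuracy
        rng = np.random.default_rng(1)
        k, n = 6, 60_000
        truth = list(rng.integers(0, k, size=n))
        preds = list(rng.integers(0, k, size=n))
        _, acc = multiclass_confusion(truth, preds)
        se = math.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(acc - 1 / k) < 4 * se


class TestBuildOgPairs:
    def _table(self, sizes, prefix="g"):
        return {
            f"{prefix}{i}": [f"{prefix}{i}_m{j}" for j in range(size)]
            for i, size in enumerate(sizes)
        }

    def test_five_member_group_yields_ten_homologous_pairs(self):
        pairs = build_og_pairs(self._table([5, 5]), np.random.default_rng(0))
        homologous = [p for p in pairs if p.homologous and p.group_id == "g0"]
        assert len(homologous) == 10

    def test_balanced_per_group(self):
        pairs = build_og_pairs(self._table([5, 4, 3]), np.random.default_rng(1))
        for gid in ("g0", "g1", "g2"):
            hom = sum(p.homologous for p in pairs if p.group_id == gid)
            non = sum(not p.homologous for p in pairs if p.group_id == gid)
            assert hom == non

    @pytest.mark.parametrize("n", range(2, 9))
    def test_pair_count_matches_enumeration(self, n):
        table = self._table([n, 3])
        pairs = build_og_pairs(table, np.random.default_rng(2))
        hom = [p for p in pairs if p.homologous and p.group_id == "g0"]
        expected = list(itertools.combinations(table["g0"], 2))
        assert len(hom) == len(expected) == n * (n - 1) // 2

    def test_nonhomologous_partners_from_other_groups(self):
        pairs = build_og_pairs(self._table([4, 4, 4]), np.random.default_rng(3))
        for p in pairs:
            if not p.homologous:
                assert p.seq_b_id.split("_")[0] != p.seq_a_id.split("_")[0]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            build_og_pairs(self._table([5]), np.random.default_rng(4))


def _sw_oracle(a, b, match=1.0, mismatch=0.0, gap_open=-10.0, gap_extend=-1.0):
    """Independent affine-gap local alignment DP (Gotoh three-state)."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, :] = M[:, 0] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            M[i, j] = max(0.0, M[i - 1, j - 1] + s, X[i - 1, j - 1] + s, Y[i - 1, j - 1] + s)
            best = max(best, M[i, j])
    return best


class TestSmithWaterman:
    def test_self_alignment_scores_length(self):
        seq = "ACGTACGTTGCA"
        assert smith_waterman_score(seq, seq) == len(seq)

    def test_disjoint_sequences_score_zero(self):
        assert smith_waterman_score("AAAA", "CCCC") == 0.0

    def test_symmetry(self):
        a, b = "ACGTACGTAA", "TTACGTGGCA"
        assert smith_waterman_score(a, b) == smith_waterman_score(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman_score("", "ACGT")

    def test_param_invariant(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=-1, gap_extend=-10)

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        bases = list("ACGT")
        for _ in range(100):
            a = "".join(rng.choice(bases, size=30))
            b = "".join(rng.choice(bases, size=30))
            assert smith_waterman_score(a, b) == pytest.approx(_sw_oracle(a, b))

    def test_monotone_in_match_score(self):
        rng = np.random.default_rng(6)
        a = "".join(rng.choice(list("ACGT"), size=40))
        b = "".join(rng.choice(list("ACGT"), size=40))
        scores = [
            smith_waterman_score(a, b, AlignmentParams(match=m))
            for m in (1.0, 2.0, 3.0)
        ]
        assert scores[0] <= scores[1] <= scores[2]


def _sweep_oracle(pairs, grid):
    rows = []
    for t in grid:
        tp = sum(p.homologous and p.embedding_similarity >= t for p in pairs)
        fp = sum((not p.homologous) and p.embedding_similarity >= t for p in pairs)
        tn = sum((not p.homologous) and p.embedding_similarity < t for p in pairs)
        fn = sum(p.homologous and p.embedding_similarity < t for p in pairs)
        rows.append((tp + tn) / len(pairs))
    return rows


class TestThresholdSweep:
    def _pairs(self, sims, labels):
        return [
            PairRecord(f"a{i}", f"b{i}", bool(l), embedding_similarity=s)
            for i, (s, l) in enumerate(zip(sims, labels))
        ]

    def test_perfect_separation(self):
        pairs = self._pairs([0.9] * 5 + [0.1] * 5, [1] * 5 + [0] * 5)
        table, best = threshold_sweep(pairs)
        assert table["accuracy"].max() == 1.0
        assert best <= 0.9

    def test_uninformative_similarity_near_chance(self):
        rng = np.random.default_rng(7)
        sims = rng.uniform(-1, 1, size=400)
        labels = rng.integers(0, 2, size=400)
        table, _ = threshold_sweep(self._pairs(sims, labels))
        assert table["accuracy"].max() <= 0.58  # majority + sampling noise only

    def test_matches_bruteforce_enumeration(self):
        pairs = self._pairs([0.85, 0.6, 0.3, -0.2, 0.61, 0.59], [1, 1, 0, 0, 1, 0])
        grid = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.01), 10)
        table, best = threshold_sweep(pairs, grid)
        oracle = _sweep_oracle(pairs, grid)
        assert np.allclose(table["accuracy"].to_numpy(), oracle)
        # tie broken toward the smallest threshold
        best_acc = max(oracle)
        first = grid[int(np.argmax(oracle))]
        assert best == pytest.approx(first)

    def test_best_accuracy_at_least_majority_fraction(self):
        rng = np.random.default_rng(8)
        sims = rng.uniform(-1, 1, size=100)
        labels = rng.random(size=100) < 0.7
        majority = max(labels.mean(), 1 - labels.mean())
        table, _ = threshold_sweep(self._pairs(sims, labels))
        assert table["accuracy"].max() >= majority - 1e-12

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, r2 = pearson_r2(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, r2 = pearson_r2(x, -x)
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2, 4, 4.5, 6, 7, 8, 9.5, 10, 12])
        y = np.array([2.0, 1, 5, 6, 5.5, 8, 7, 10, 9, 11])
        r, r2 = pearson_r2(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
        assert r == pytest.approx(expected, abs=1e-10)
        assert r2 == pytest.approx(expected**2, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestManova:
    def test_identical_groups_zero_trace(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        data = np.vstack([X, X])
        groups = ["a"] * 10 + ["b"] * 10
        res = manova_pillai(data, groups)
        assert res.pillai == pytest.approx(0.0, abs=1e-10)

    def test_separated_clouds_significant_both_ways(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 1.0, size=(50, 4))
        b = rng.normal(3.0, 1.0, size=(50, 4))
        res = manova_pillai(np.vstack([a, b]), ["a"] * 50 + ["b"] * 50,
                            permutations=999, rng=np.random.default_rng(11))
        assert res.p_value < 0.001
        assert res.permutation_p < 0.005  # permutation floor is 1/1000

    def test_matches_statsmodels_pillai(self):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        import pandas as pd

        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 3))
        X[:20] += 0.8
        groups = ["a"] * 20 + ["b"] * 20
        res = manova_pillai(X, groups)
        df = pd.DataFrame(X, columns=["v0", "v1", "v2"])
        df["g"] = groups
        fit = sm_manova.MANOVA.from_formula("v0 + v1 + v2 ~ g", data=df)
        table = fit.mv_test().results["g"]["stat"]
        assert res.pillai == pytest.approx(float(table.loc["Pillai's trace", "Value"]), abs=1e-6)
        assert res.p_value == pytest.approx(float(table.loc["Pillai's trace", "Pr > F"]), abs=1e-6)

    def test_null_pvalues_uniform(self):
        # 200 null datasets; the F-approximation p-values should pass a KS
        # test against Uniform(0,1) at alpha = 0.01
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            X = rng.normal(size=(30, 4))
            groups = ["a"] * 15 + ["b"] * 15
            pvals.append(manova_pillai(X, groups).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            manova_pillai(np.ones((3, 2)), ["a", "a", "b"])


def test_metrics_from_confusion_empty_rejected():
    with pytest.raises(ValueError):
        metrics_from_confusion(ConfusionMatrix())


def test_pairs_tsv_round_trip(tmp_path):
    pairs = [
        PairRecord("a", "b", True, embedding_similarity=0.7, alignment_score=33.0, group_id="g0"),
        PairRecord("c", "d", False, embedding_similarity=-0.1, alignment_score=0.0, group_id="g0"),
    ]
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv(pairs, path)
    back = read_pairs_tsv(path)
    assert [(p.seq_a_id, p.homologous, p.embedding_similarity) for p in back] == [
        (p.seq_a_id, p.homologous, p.embedding_similarity) for p in pairs
    ]
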