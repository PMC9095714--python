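"""Evaluation statistics: confusion metrics, homolog pairs, alignment scores,
threshold sweeps, correlation, and multivariate group separation.

Binary classification metrics follow the usual confusion-count definitions —
accuracy (TP+TN)/(TP+FP+TN+FN), precision TP/(TP+FP), recall TP/(TP+FN), and
F1 as the harmonic mean of precision and recall. Homology evaluation builds
balanced sets of homologous (within orthologous group) and nonhomologous
(across groups) sequence pairs, scores each pair by embedding cosine
similarity and Smith-Waterman local alignment (gap open -10, gap extension
-1), and sweeps a similarity threshold to find the maximum-accuracy decision
rule. Group separation of embedding vectors is tested by one-way MANOVA
(Pillai's trace) with either the classical F approximation or a permutation
p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats as sps


@dataclass
class ConfusionMatrix:
    """Binary confusion counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Accuracy, precision, recall, F1 — all fractions in [0, 1].

    A metric whose denominator is zero is reported as 0.0 and flagged in
    ``undefined``.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: list[str] = field(default_factory=list)


@dataclass
class PairRecord:
    """A sequence pair with homology label and both similarity scores."""

    seq_a_id: str
    seq_b_id: str
    homologous: bool
    embedding_similarity: float = math.nan
    alignment_score: float = math.nan
    group_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.embedding_similarity) and not -1 <= self.embedding_similarity <= 1:
            raise ValueError("embedding similarity must lie in [-1, 1]")


@dataclass
class AlignmentParams:
    """Local-alignment scoring: affine gaps, open charged on the first gap
    position and extension on each subsequent one."""

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("need gap_open <= gap_extend <= 0")


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    undefined = []
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return MetricsReport(accuracy, precision, recall, f1, undefined)


def confusion_and_metrics(
    truth: Sequence, predictions: Sequence, positive_label
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Binary confusion counts and metrics, treating ``positive_label`` as positive."""
    if len(truth) != len(predictions):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(predictions)} predictions")
    if len(truth) == 0:
        raise ValueError("cannot evaluate zero items")
    cm = ConfusionMatrix()
    for t, p in zip(truth, predictions):
        if t == positive_label:
            if p == positive_label:
                cm.tp += 1
            else:
                cm.fn += 1
        else:
            if p == positive_label:
                cm.fp += 1
            else:
                cm.tn += 1
    return cm, metrics_from_confusion(cm)


def multiclass_confusion(truth: Sequence, predictions: Sequence) -> tuple[pd.DataFrame, float]:
    """K x K confusion table (rows = truth) and overall accuracy."""
    if len(truth) != len(predictions):
        raise ValueError("length mismatch")
    if len(truth) == 0:
        raise ValueError("cannot evaluate zero items")
    labels = sorted(set(truth) | set(predictions))
    t = pd.Categorical(list(truth), categories=labels)
    p = pd.Categorical(list(predictions), categories=labels)
    table = pd.crosstab(t, p, dropna=False)
    table.index = table.index.astype(object)
    table.columns = table.columns.astype(object)
    accuracy = float(np.trace(table.to_numpy()) / len(truth))
    return table, accuracy


def build_og_pairs(
    og_table: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> list[PairRecord]:
    """Balanced homologous/nonhomologous pairs from orthologous groups.

    All unordered member pairs within a group are homologous (a 5-member
    group yields 10); an equal number of nonhomologous pairs is drawn by
    pairing the group's members, in rotation, with randomly selected members
    of other randomly selected groups.
    """
    groups = sorted(og_table)
    if len(groups) < 2:
        raise ValueError("need at least two groups to form nonhomologous pairs")
    for gid in groups:
        if len(og_table[gid]) < 2:
            raise ValueError(f"group {gid!r} has fewer than 2 members")
    pairs: list[PairRecord] = []
    for gi, gid in enumerate(groups):
        members = list(og_table[gid])
        homologous = list(itertools.combinations(members, 2))
        for a, b in homologous:
            pairs.append(PairRecord(a, b, True, group_id=gid))
        others = [g for g in groups if g != gid]
        for k in range(len(homologous)):
            a = members[k % len(members)]
            other = others[int(rng.integers(0, len(others)))]
            partner_pool = og_table[other]
            b = partner_pool[int(rng.integers(0, len(partner_pool)))]
            pairs.append(PairRecord(a, b, False, group_id=gid))
    return pairs


def smith_waterman_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal local alignment score under affine gap penalties.

    Defaults: match +1, mismatch 0, gap open -10, gap extension -1. The score
    of a local alignment is never negative (the empty alignment scores 0) and
    is symmetric in its arguments.
    """
    if params is None:
        params = AlignmentParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return float(aligner.score(a.upper(), b.upper()))


def threshold_sweep(
    pairs: Sequence[PairRecord],
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Sweep a similarity threshold over pairs; homologous iff similarity >= t.

    Returns a per-threshold table of accuracy/precision/recall/F1 and the
    maximum-accuracy threshold (ties broken toward the smallest threshold).
    """
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    if grid is None:
        grid = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.01), 10)
    sims = np.array([p.embedding_similarity for p in pairs])
    labels = np.array([p.homologous for p in pairs])
    rows = []
    for t in grid:
        pred = sims >= t
        cm = ConfusionMatrix(
            tp=int((pred & labels).sum()),
            fp=int((pred & ~labels).sum()),
            tn=int((~pred & ~labels).sum()),
            fn=int((~pred & labels).sum()),
        )
        m = metrics_from_confusion(cm)
        rows.append((float(t), m.accuracy, m.precision, m.recall, m.f1))
    table = pd.DataFrame(rows, columns=["threshold", "accuracy", "precision", "recall", "f1"])
    best_idx = int(table["accuracy"].to_numpy().argmax())  # argmax returns first = smallest t
    return table, float(table["threshold"].iloc[best_idx])


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


@dataclass
class ManovaResult:
    pillai: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    permutation_p: float | None = None


def _pillai(X: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = X.mean(axis=0)
    p = X.shape[1]
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in range(n_groups):
        sub = X[codes == g]
        mean_g = sub.mean(axis=0)
        diff = (mean_g - grand)[:, None]
        H += len(sub) * (diff @ diff.T)
        centered = sub - mean_g
        E += centered.T @ centered
    T = H + E
    try:
        sol = np.linalg.solve(T, H)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular total scatter matrix; use the permutation mode"
        ) from err
    return float(np.trace(sol))


def manova_pillai(
    vectors: np.ndarray,
    groups: Sequence,
    permutations: int | None = None,
    rng: np.random.Generator | None = None,
) -> ManovaResult:
    """One-way MANOVA via Pillai's trace V = tr(H (H+E)^-1).

    The classical F approximation is always computed when the scatter solve is
    well-posed; with ``permutations`` set (>= 999 recommended) a permutation
    p-value is additionally estimated by shuffling group labels.
    """
    X = np.asarray(vectors, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    for gi in range(g):
        if (codes == gi).sum() < 2:
            raise ValueError("every group needs at least two members")
    N, p = X.shape
    V = _pillai(X, codes, g)
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2
    n = (N - g - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n + s + 1)
    if df2 <= 0:
        raise ValueError("too few samples for the F approximation; use permutations")
    f_stat = (2 * n + s + 1) / (2 * m + s + 1) * (V / s) / (1 - V / s)
    p_value = float(sps.f.sf(f_stat, df1, df2))
    perm_p = None
    if permutations:
        if rng is None:
            rng = np.random.default_rng()
        exceed = 0
        for _ in range(permutations):
            if _pillai(X, rng.permutation(codes), g) >= V:
                exceed += 1
        perm_p = (1 + exceed) / (permutations + 1)
    return ManovaResult(V, f_stat, df1, df2, p_value, perm_p)


def write_pairs_tsv(pairs: Sequence[PairRecord], path) -> None:
    rows = [
        (p.seq_a_id, p.seq_b_id, p.group_id or "", int(p.homologous),
         p.embedding_similarity, p.alignment_score)
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=["seq_a_id", "seq_b_id", "group_id", "homologous",
                 "embedding_similarity", "alignment_score"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[PairRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PairRecord(
            seq_a_id=str(r.seq_a_id), seq_b_id=str(r.seq_b_id),
            homologous=bool(r.homologous),
            embedding_similarity=float(r.embedding_similarity),
            alignment_score=float(r.alignment_score),
            group_id=str(r.group_id) or None,
        )
        for r in df.itertuples()
    ]
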