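"""Hierarchical multi-label evaluation: PR curves, AU(PRC), rank comparison.

Predictions are compared threshold-free.  Sweeping a threshold t over the
class scores produces, at each t, pooled (micro-averaged) precision and
recall counts

    Prec = ΣTP_i / (ΣTP_i + ΣFP_i),   Rec = ΣTP_i / (ΣTP_i + ΣFN_i)

summed over the class scope.  The union of the points over all thresholds is
the PR curve; its area is computed with count-space (Davis–Goadrich style)
interpolation — between consecutive achievable count pairs (TP_a, FP_a) and
(TP_b, FP_b) the false positives are interpolated linearly in TP, one unit
of TP at a time, which avoids the optimistic bias of connecting PR points
with straight lines in PR space.

Before counting, thresholded predictions are consistency-repaired against
the hierarchy, so the evaluation measures exactly the label sets a user
would receive.  Thresholding at t after cascading repair keeps a class iff
the minimum score along its root path is ≥ t, so curves are computed on the
min-path-transformed scores (the literal threshold-then-repair route is kept
in :func:`pr_point` and checked against this one in the tests).

Per-class areas (AUPRC_i) are averaged either weighted by class frequency,
w_i = v_i/Σv_j, or uniformly with w_i = 1/|C|.  Methods are compared across
datasets by Friedman average ranks with the Nemenyi critical difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, studentized_range

from .hierarchy import ClassHierarchy

__all__ = [
    "PRPoint",
    "PRCurve",
    "ClassWeights",
    "MetricReport",
    "pr_point",
    "pr_curve",
    "au_prc_micro",
    "per_class_auprc",
    "auprc_weighted",
    "evaluate_model",
    "average_ranks",
    "nemenyi_cd",
    "per_class_wins",
]


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 1.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0


@dataclass
class PRCurve:
    points: list[PRPoint]
    area: float
    scope: np.ndarray  # class column indices the counts were pooled over


@dataclass
class ClassWeights:
    """Per-class weights for averaging per-class PR areas."""

    weights: dict[str, float]
    mode: str  # "frequency" | "uniform"

    @classmethod
    def frequency(cls, Y: np.ndarray, hierarchy: ClassHierarchy,
                  scope_ids: list[str]) -> "ClassWeights":
        """w_i = v_i / Σ_j v_j with v_i the class frequency in the closed
        label matrix ``Y``."""
        freqs = {
            cid: float(Y[:, hierarchy.index_of(cid)].sum()) for cid in scope_ids
        }
        total = sum(freqs.values())
        if total == 0:
            raise ValueError("no positive labels in scope")
        return cls({c: v / total for c, v in freqs.items()}, "frequency")

    @classmethod
    def uniform(cls, scope_ids: list[str]) -> "ClassWeights":
        n = len(scope_ids)
        return cls({c: 1.0 / n for c in scope_ids}, "uniform")


def _resolve_scope(
    hierarchy: ClassHierarchy, scope: np.ndarray | list | None
) -> np.ndarray:
    if scope is None:
        return np.arange(hierarchy.class_count, dtype=np.intp)
    scope = list(scope)
    if scope and isinstance(scope[0], str):
        return np.array([hierarchy.index_of(c) for c in scope], dtype=np.intp)
    return np.asarray(scope, dtype=np.intp)


def pr_point(
    scores: np.ndarray,
    truth: np.ndarray,
    hierarchy: ClassHierarchy,
    threshold: float,
    scope: np.ndarray | list | None = None,
) -> PRPoint:
    """Pooled TP/FP/FN at one threshold, after consistency repair.

    Predictions are (score ≥ threshold) repaired over the *full* hierarchy;
    counts are then pooled over the scope columns only.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    truth = np.atleast_2d(np.asarray(truth))
    if scores.shape != truth.shape:
        raise ValueError("scores and truth shapes differ")
    cols = _resolve_scope(hierarchy, scope)
    pred = hierarchy.repair_consistency((scores >= threshold).astype(np.int8))
    p = pred[:, cols].astype(bool)
    t = truth[:, cols].astype(bool)
    TP = int(np.sum(p & t))
    FP = int(np.sum(p & ~t))
    FN = int(np.sum(~p & t))
    return PRPoint(threshold=float(threshold), TP=TP, FP=FP, FN=FN)


def _curve_counts(pooled_scores: np.ndarray, pooled_truth: np.ndarray):
    """Achievable (threshold, TP, FP) triples, thresholds descending."""
    order = np.argsort(-pooled_scores, kind="stable")
    s = pooled_scores[order]
    t = pooled_truth[order].astype(np.int64)
    cum_tp = np.cumsum(t)
    cum_fp = np.cumsum(1 - t)
    # last index of each distinct score = counts at that threshold
    last = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    # the lowest distinct score already predicts everything, so the
    # threshold-0 endpoint adds no new achievable point
    return s[last], cum_tp[last], cum_fp[last]


def _dg_area(TP: np.ndarray, FP: np.ndarray, total_pos: int) -> float:
    """Area under the count-interpolated curve, anchored at (0, 0) counts.

    One rectangle of width 1/total_pos per unit of TP, at the precision of
    the linearly count-interpolated point.  Interpolating from the (0, 0)
    anchor reduces, for the first segment, to a constant extension of the
    first achievable point's precision back to recall 0.
    """
    TP = np.concatenate([[0], TP]).astype(np.int64)
    FP = np.concatenate([[0], FP]).astype(float)
    dTP = np.diff(TP)
    dFP = np.diff(FP)
    if TP[-1] == 0:
        return 0.0
    slope = np.divide(dFP, dTP, out=np.zeros_like(dFP), where=dTP > 0)
    seg = np.repeat(np.arange(len(dTP)), dTP)  # one entry per unit of TP
    j = np.arange(1, TP[-1] + 1, dtype=float)
    fp_interp = FP[:-1][seg] + (j - TP[:-1][seg]) * slope[seg]
    prec = j / (j + fp_interp)
    return float(prec.sum() / total_pos)


def _step_area(TP: np.ndarray, FP: np.ndarray, total_pos: int) -> float:
    """Fine-grid fallback: step function through the achievable points
    (each recall increment earns the precision of the point that achieves
    it, with no interpolation inside tied-score blocks)."""
    TP = np.concatenate([[0], TP]).astype(float)
    FP = np.concatenate([[0], FP]).astype(float)
    denom = TP[1:] + FP[1:]
    prec = np.where(denom > 0, TP[1:] / np.where(denom > 0, denom, 1), 1.0)
    return float(np.sum(np.diff(TP) / total_pos * prec))


def pr_curve(
    scores: np.ndarray,
    truth: np.ndarray,
    hierarchy: ClassHierarchy,
    scope: np.ndarray | list | None = None,
    method: str = "interpolated",
) -> PRCurve:
    """Pooled PR curve over the scope, swept at every distinct score.

    Scores are min-path transformed first (threshold + repair equivalence),
    so the curve matches what repeated :func:`pr_point` calls would count.
    ``method`` selects the area rule: ``"interpolated"`` (count-space
    interpolation, default) or ``"step"`` (no interpolation).  The two can
    differ visibly when the min-path transform creates large tied-score
    blocks: interpolation spreads a block's recall gain over intermediate
    precisions while the step rule credits the block's final precision.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    truth = np.atleast_2d(np.asarray(truth))
    cols = _resolve_scope(hierarchy, scope)
    repaired = hierarchy.min_path_scores(scores)
    s = repaired[:, cols].ravel()
    t = truth[:, cols].ravel().astype(bool)
    total_pos = int(t.sum())
    if total_pos == 0:
        raise ValueError("PR curve undefined: no positive labels in scope")
    thresholds, TP, FP = _curve_counts(s, t)
    if method == "interpolated":
        area = _dg_area(TP, FP, total_pos)
    elif method == "step":
        area = _step_area(TP, FP, total_pos)
    else:
        raise ValueError(f"unknown area method {method!r}")
    points = [  # thresholds descending <=> recall non-decreasing
        PRPoint(float(th), int(tp), int(fp), int(total_pos - tp))
        for th, tp, fp in zip(thresholds, TP, FP)
    ]
    return PRCurve(points=points, area=area, scope=cols)


def au_prc_micro(
    scores: np.ndarray,
    truth: np.ndarray,
    hierarchy: ClassHierarchy,
    scope: np.ndarray | list | None = None,
    method: str = "interpolated",
) -> float:
    """Area under the pooled (micro-averaged) PR curve over the scope."""
    return pr_curve(scores, truth, hierarchy, scope, method=method).area


def per_class_auprc(
    scores: np.ndarray,
    truth: np.ndarray,
    hierarchy: ClassHierarchy,
) -> tuple[dict[str, float], list[str]]:
    """AUPRC_i per class; classes without positives are excluded and listed."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    truth = np.atleast_2d(np.asarray(truth))
    repaired = hierarchy.min_path_scores(scores)
    areas: dict[str, float] = {}
    excluded: list[str] = []
    for cid in hierarchy.class_ids:
        j = hierarchy.index_of(cid)
        t = truth[:, j].astype(bool)
        pos = int(t.sum())
        if pos == 0:
            excluded.append(cid)
            continue
        _, TP, FP = _curve_counts(repaired[:, j], t)
        areas[cid] = _dg_area(TP, FP, pos)
    return areas, excluded


def auprc_weighted(
    areas: dict[str, float], weights: ClassWeights
) -> float:
    """Σ w_i · AUPRC_i over the evaluated classes."""
    if set(areas) != set(weights.weights):
        raise ValueError("weight/area class sets differ")
    return float(sum(weights.weights[c] * a for c, a in areas.items()))


@dataclass
class MetricReport:
    """Summary metrics for one score matrix against one truth matrix."""

    au_prc_micro: float
    auprc_weighted: float
    auprc_uniform: float
    per_class: dict[str, float]
    per_level: dict[int, float | None]
    excluded_classes: list[str]

    def summary(self) -> dict[str, float]:
        return {
            "au_prc_micro": self.au_prc_micro,
            "auprc_weighted": self.auprc_weighted,
            "auprc_uniform": self.auprc_uniform,
        }


def evaluate_model(
    scores: np.ndarray,
    truth: np.ndarray,
    hierarchy: ClassHierarchy,
) -> MetricReport:
    """Compute the full metric battery for one prediction run."""
    truth = np.atleast_2d(np.asarray(truth))
    areas, excluded = per_class_auprc(scores, truth, hierarchy)
    evaluated = list(areas)
    w_freq = ClassWeights.frequency(truth, hierarchy, evaluated)
    w_unif = ClassWeights.uniform(evaluated)
    per_level: dict[int, float | None] = {}
    for l in range(1, hierarchy.max_depth + 1):
        cols = hierarchy.levels[l]
        if truth[:, cols].sum() == 0:
            per_level[l] = None
        else:
            per_level[l] = au_prc_micro(scores, truth, hierarchy, cols)
    return MetricReport(
        au_prc_micro=au_prc_micro(scores, truth, hierarchy),
        auprc_weighted=auprc_weighted(areas, w_freq),
        auprc_uniform=auprc_weighted(areas, w_unif),
        per_class=areas,
        per_level=per_level,
        excluded_classes=excluded,
    )


# ---------------------------------------------------------------------------
# Rank-based method comparison
# ---------------------------------------------------------------------------

def average_ranks(table: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Friedman average ranks of methods (columns) across datasets (rows).

    Methods are ranked per dataset in descending metric order (rank 1 =
    best); ties receive the average of the tied positions; ranks are then
    averaged over datasets.
    """
    values = np.asarray(table, dtype=float)
    if np.isnan(values).any():
        raise ValueError("metric table contains missing cells")
    ranks = np.vstack([rankdata(-row, method="average") for row in values])
    mean = ranks.mean(axis=0)
    if isinstance(table, pd.DataFrame):
        return pd.Series(mean, index=table.columns, name="mean_rank")
    return mean


def nemenyi_cd(k: int, n_datasets: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference: CD = q_α · sqrt(k(k+1) / (6N)).

    Two methods differ significantly when their mean-rank gap is ≥ CD.
    q_α is the studentized-range quantile at infinite df divided by √2.
    """
    if k < 2 or n_datasets < 2:
        raise ValueError("need at least 2 methods and 2 datasets")
    if alpha not in (0.05, 0.10):
        raise ValueError("alpha must be 0.05 or 0.10")
    q = studentized_range.ppf(1.0 - alpha, k, np.inf) / math.sqrt(2.0)
    return float(q * math.sqrt(k * (k + 1) / (6.0 * n_datasets)))


def significance_matrix(
    mean_ranks: pd.Series, n_datasets: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Boolean matrix: |rank_a − rank_b| ≥ CD for each method pair."""
    cd = nemenyi_cd(len(mean_ranks), n_datasets, alpha)
    diff = np.abs(mean_ranks.values[:, None] - mean_ranks.values[None, :])
    return pd.DataFrame(diff >= cd, index=mean_ranks.index,
                        columns=mean_ranks.index)


def per_class_wins(
    areas_a: pd.DataFrame,
    areas_b: pd.DataFrame,
    min_wins: int,
) -> tuple[list[str], list[str]]:
    """Classes where one method beats the other in ≥ ``min_wins`` datasets.

    Both frames are datasets × classes grids of per-class AUPRC values.
    Returns (best, worst): classes where A > B (resp. B > A) in at least
    ``min_wins`` datasets; exact ties count for neither side.
    """
    if not areas_a.index.equals(areas_b.index) or not areas_a.columns.equals(
        areas_b.columns
    ):
        raise ValueError("method grids are not aligned")
    a_wins = (areas_a.values > areas_b.values).sum(axis=0)
    b_wins = (areas_b.values > areas_a.values).sum(axis=0)
    best = [c for c, w in zip(areas_a.columns, a_wins) if w >= min_wins]
    worst = [c for c, w in zip(areas_a.columns, b_wins) if w >= min_wins]
    return best, worst
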