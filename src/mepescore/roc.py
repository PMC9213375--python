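"""ROC analysis for small ordinal risk scores.

Operating points are taken at the achievable cutoffs of the score with the
strict convention "call positive when score > t" — for a 1-5 score the
usable thresholds are the observed score values themselves.  The AUC is the
trapezoidal area, which for this construction equals the tie-corrected
Mann-Whitney concordance probability P(score+ > score-) + P(tie)/2.

Confidence intervals and paired/unpaired AUC comparisons use DeLong's
placement-value variance estimator (Hanley-McNeil offered as an option).
The operating threshold is chosen by the triple criterion: maximize the
harmonic mean of Se and Sp, maximize Youden's J = Se + Sp - 1, and minimize
the Euclidean distance to the perfect corner Se = Sp = 1.  When the three
disagree the Youden maximizer is reported with ``agreed=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "OperatingPoint",
    "RocAnalysis",
    "ThresholdSelection",
    "roc_curve",
    "select_threshold",
    "compare_auc_paired",
    "compare_auc_unpaired",
]


@dataclass(frozen=True)
class OperatingPoint:
    """Se/Sp at one strict cutoff ("positive iff score > threshold")."""

    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocAnalysis:
    """An empirical ROC curve over an ordinal score."""

    operating_points: tuple[OperatingPoint, ...]
    auc: float
    auc_ci: tuple[float, float]
    auc_se: float
    n_pos: int
    n_neg: int
    ci_level: float = 0.95

    @property
    def thresholds(self) -> list[float]:
        return [p.threshold for p in self.operating_points]


@dataclass(frozen=True)
class CriterionRow:
    """The three threshold-selection criteria evaluated at one cutoff."""

    threshold: float
    sensitivity: float
    specificity: float
    harmonic_mean: float
    youden_j: float
    corner_distance: float


@dataclass(frozen=True)
class ThresholdSelection:
    """Result of the triple-criterion operating-threshold choice."""

    harmonic_mean_threshold: float
    youden_threshold: float
    corner_threshold: float
    agreed: bool
    selected: float
    criteria_values: tuple[CriterionRow, ...]


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-case concordance against the other class."""
    # V10[i] = P(score_i > neg) + P(tie)/2 over negatives, and symmetrically.
    v10 = np.empty(pos.size)
    v01 = np.empty(neg.size)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / neg.size
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / pos.size
    return v10, v01


def _delong_var(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if pos.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if neg.size > 1 else 0.0
    return auc, s10 / pos.size + s01 / neg.size


def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def _split_classes(
    scores: Sequence[float], truths: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("scores and truths must have equal length")
    pos, neg = s[t], s[~t]
    if pos.size == 0:
        raise ValueError("no truth-positive cases: ROC undefined")
    if neg.size == 0:
        raise ValueError("no truth-negative cases: ROC undefined")
    return pos, neg


def roc_curve(
    scores: Sequence[float],
    truths: Sequence[bool],
    ci_level: float = 0.95,
    ci_method: Literal["delong", "hanley-mcneil"] = "delong",
) -> RocAnalysis:
    """Empirical ROC of an ordinal score against dichotomous truth.

    One operating point per distinct observed score value t, calling
    positive when score > t (so the highest t gives Se = 0, Sp = 1).  The
    reported AUC is the trapezoid over the full polyline from (0,0) to
    (1,1), identical to the all-pairs concordance probability.
    """
    pos, neg = _split_classes(scores, truths)
    thresholds = np.unique(np.concatenate([pos, neg]))
    points = []
    for t in thresholds:
        se = float(np.mean(pos > t))
        sp = float(np.mean(neg <= t))
        points.append(OperatingPoint(float(t), se, sp))

    auc, var = _delong_var(pos, neg)
    if ci_method == "hanley-mcneil":
        var = _hanley_mcneil_var(auc, pos.size, neg.size)
    elif ci_method != "delong":
        raise ValueError(f"unknown AUC CI method {ci_method!r}")
    se_auc = math.sqrt(var)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    ci = (max(0.0, auc - z * se_auc), min(1.0, auc + z * se_auc))
    return RocAnalysis(
        operating_points=tuple(points),
        auc=auc,
        auc_ci=ci,
        auc_se=se_auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        ci_level=ci_level,
    )


def select_threshold(curve: RocAnalysis) -> ThresholdSelection:
    """Triple-criterion threshold choice over the curve's achievable cutoffs.

    Computes, at every operating point, the harmonic mean of Se and Sp,
    Youden's J, and the distance to the (1, 1) corner; each criterion picks
    its optimum and ``agreed`` records whether all three coincide.  On
    disagreement the Youden maximizer is selected (the only criterion the
    source convention defines by an explicit formula); ties within a
    criterion go to the lower threshold (favouring sensitivity).
    """
    if len(curve.operating_points) < 2:
        raise ValueError("threshold selection needs >= 2 operating points")
    rows = []
    for p in curve.operating_points:
        se, sp = p.sensitivity, p.specificity
        hm = 0.0 if se + sp == 0 else 2 * se * sp / (se + sp)
        rows.append(
            CriterionRow(
                threshold=p.threshold,
                sensitivity=se,
                specificity=sp,
                harmonic_mean=hm,
                youden_j=se + sp - 1,
                corner_distance=math.hypot(1 - se, 1 - sp),
            )
        )
    hm_t = max(rows, key=lambda r: (r.harmonic_mean, -r.threshold)).threshold
    j_t = max(rows, key=lambda r: (r.youden_j, -r.threshold)).threshold
    d_t = min(rows, key=lambda r: (r.corner_distance, r.threshold)).threshold
    agreed = hm_t == j_t == d_t
    return ThresholdSelection(
        harmonic_mean_threshold=hm_t,
        youden_threshold=j_t,
        corner_threshold=d_t,
        agreed=agreed,
        selected=j_t,
        criteria_values=tuple(rows),
    )


def compare_auc_paired(
    scores1: Sequence[float],
    scores2: Sequence[float],
    truths: Sequence[bool],
) -> tuple[float, float]:
    """DeLong test for two AUCs measured on the same patients.

    Returns (AUC1 - AUC2, two-sided p).  Antisymmetric in score order: the
    delta flips sign, the p-value is unchanged.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    t = np.asarray(truths, dtype=bool)
    if not (s1.shape == s2.shape == t.shape):
        raise ValueError("paired comparison needs equal-length score/truth vectors")
    pos1, neg1 = s1[t], s1[~t]
    pos2, neg2 = s2[t], s2[~t]
    if pos1.size == 0 or neg1.size == 0:
        raise ValueError("both classes must be present")
    v10_1, v01_1 = _placements(pos1, neg1)
    v10_2, v01_2 = _placements(pos2, neg2)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = pos1.size, neg1.size
    # 2x2 covariance of the placement means across the two scores
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc1 - auc2
    if var_delta <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / math.sqrt(var_delta)
    return delta, float(2 * stats.norm.sf(abs(z)))


def compare_auc_unpaired(curve_a: RocAnalysis, curve_b: RocAnalysis) -> float:
    """Two-sided z-test of AUCs from disjoint cohorts via their DeLong SEs."""
    se = math.hypot(curve_a.auc_se, curve_b.auc_se)
    if se == 0:
        return 1.0 if curve_a.auc == curve_b.auc else 0.0
    z = (curve_a.auc - curve_b.auc) / se
    return float(2 * stats.norm.sf(abs(z)))
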