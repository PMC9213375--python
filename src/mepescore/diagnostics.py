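"""Diagnostic-accuracy statistics against pathologic ground truth.

Everything here reduces to a 2x2 contingency table of a dichotomous
predictor (an MRI feature, or a dichotomized score) against pathologic
extraprostatic extension (pEPE).  From a table we compute detection rate,
sensitivity, specificity, PPV, NPV and accuracy, each with a Wald 95% CI
clipped to [0, 1] (Wilson and Clopper-Pearson available as options), the
cross-product odds ratio with its log-scale Wald interval, and the
equivalent univariate binary logistic regression.  A zero cell makes the
odds ratio "not determined" (interval 0 to infinity) rather than a
continuity-corrected number; a Haldane-Anscombe +0.5 correction is
available behind a flag.

Cohort-comparison helpers (Fisher's exact test for dichotomous variables,
Mann-Whitney for continuous ones) live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "ProportionCI",
    "DiagnosticSummary",
    "build_contingency",
    "proportion_ci",
    "diagnostic_summary",
    "odds_ratio_2x2",
    "univariate_blr",
    "ordinal_blr",
    "fisher_exact",
    "mann_whitney",
    "NOT_DETERMINED",
]

#: Sentinel for odds ratios whose Wald interval extends from 0 to infinity.
NOT_DETERMINED = "not determined"


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts of a dichotomous predictor vs. ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Truth-positive margin (diseased)."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])

    def has_zero_cell(self) -> bool:
        return 0 in (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its confidence interval and denominator."""

    estimate: float | None
    lower: float | None
    upper: float | None
    denominator: int

    @property
    def defined(self) -> bool:
        return self.estimate is not None


_UNDEFINED = ProportionCI(None, None, None, 0)


def proportion_ci(
    k: int,
    m: int,
    ci_level: float = 0.95,
    method: Literal["wald", "wilson", "clopper-pearson"] = "wald",
) -> ProportionCI:
    """CI for a binomial proportion k/m, clipped to [0, 1].

    Wald is the default because it reproduces the study-style printed
    intervals; Wilson and Clopper-Pearson are offered for small samples.
    """
    if m == 0:
        return _UNDEFINED
    p = k / m
    if method == "wald":
        z = stats.norm.ppf(0.5 + ci_level / 2)
        half = z * math.sqrt(p * (1 - p) / m)
        lo, hi = p - half, p + half
    elif method == "wilson":
        lo, hi = stats.binomtest(k, m).proportion_ci(ci_level, method="wilson")
    elif method == "clopper-pearson":
        lo, hi = stats.binomtest(k, m).proportion_ci(ci_level, method="exact")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ProportionCI(p, max(0.0, float(lo)), min(1.0, float(hi)), m)


@dataclass(frozen=True)
class DiagnosticSummary:
    """All per-feature accuracy statistics of one 2x2 table.

    ``odds_ratio`` / ``or_ci`` are ``"not determined"`` when any cell of the
    table is zero (the Wald interval then spans 0 to infinity).
    """

    table: ContingencyTable
    detection_rate: ProportionCI
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI
    accuracy: ProportionCI
    odds_ratio: float | str
    or_ci: tuple[float, float] | str
    p_value: float
    ci_level: float


def build_contingency(
    predictions: Sequence[bool], truths: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate dichotomous predictions against ground truth."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if len(predictions) == 0:
        raise ValueError("cannot build a contingency table from empty inputs")
    pred = np.asarray(predictions, dtype=bool)
    tru = np.asarray(truths, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(pred & tru)),
        fp=int(np.sum(pred & ~tru)),
        fn=int(np.sum(~pred & tru)),
        tn=int(np.sum(~pred & ~tru)),
    )


def odds_ratio_2x2(
    table: ContingencyTable,
    ci_level: float = 0.95,
    haldane: bool = False,
) -> tuple[float, tuple[float, float]] | str:
    """Cross-product odds ratio with log-scale Wald CI.

    Equals the MLE of the univariate logistic model with one binary
    predictor.  Any zero cell returns ``"not determined"`` unless
    ``haldane`` adds 0.5 to every cell.
    """
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    if table.has_zero_cell():
        if not haldane:
            return NOT_DETERMINED
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    orr = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - z * se)
    hi = math.exp(math.log(orr) + z * se)
    return orr, (lo, hi)


def _or_p_value(table: ContingencyTable) -> float:
    """Wald p of the logistic slope; Fisher's exact when a zero cell breaks Wald."""
    if table.has_zero_cell():
        return fisher_exact(table)
    orr, _ = odds_ratio_2x2(table)
    se = math.sqrt(1 / table.tp + 1 / table.fp + 1 / table.fn + 1 / table.tn)
    z = math.log(orr) / se
    return float(2 * stats.norm.sf(abs(z)))


def diagnostic_summary(
    table: ContingencyTable,
    ci_level: float = 0.95,
    ci_method: Literal["wald", "wilson", "clopper-pearson"] = "wald",
) -> DiagnosticSummary:
    """Detection rate, Se, Sp, PPV, NPV and accuracy with CIs, plus OR block.

    Statistics with a zero denominator come back undefined
    (``ProportionCI.defined`` false), never silently zero.  The detection
    rate — the fraction of feature-positive patients who truly have pEPE —
    coincides with PPV.
    """
    if table.n == 0:
        raise ValueError("empty contingency table")
    t = table

    def ci(k: int, m: int) -> ProportionCI:
        return proportion_ci(k, m, ci_level, ci_method)

    or_res = odds_ratio_2x2(t, ci_level)
    if or_res == NOT_DETERMINED:
        orr, or_ci = NOT_DETERMINED, NOT_DETERMINED
    else:
        orr, or_ci = or_res

    return DiagnosticSummary(
        table=t,
        detection_rate=ci(t.tp, t.tp + t.fp),
        sensitivity=ci(t.tp, t.n_pos),
        specificity=ci(t.tn, t.n_neg),
        ppv=ci(t.tp, t.tp + t.fp),
        npv=ci(t.tn, t.tn + t.fn),
        accuracy=ci(t.tp + t.tn, t.n),
        odds_ratio=orr,
        or_ci=or_ci,
        p_value=_or_p_value(t),
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class BlrResult:
    """Univariate binary-logistic fit of truth on one dichotomous predictor."""

    coefficient: float | None
    odds_ratio: float | str
    p_value: float | None
    converged: bool


def univariate_blr(x: Sequence[bool], y: Sequence[bool]) -> BlrResult:
    """Maximum-likelihood logistic regression of y on intercept + x.

    For a binary predictor the fitted OR equals the table cross-product;
    complete or quasi-complete separation (a zero cell) is flagged as
    non-convergent / not determined instead of returning a runaway slope.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if len(np.unique(x)) < 2:
        return BlrResult(None, NOT_DETERMINED, None, converged=False)
    table = build_contingency(x.astype(bool), y.astype(bool))
    if table.has_zero_cell():
        return BlrResult(None, NOT_DETERMINED, None, converged=False)
    design = sm.add_constant(x)
    fit = sm.Logit(y, design).fit(disp=False)
    coef = float(fit.params[1])
    return BlrResult(
        coefficient=coef,
        odds_ratio=math.exp(coef),
        p_value=float(fit.pvalues[1]),
        converged=bool(fit.mle_retvals.get("converged", True)),
    )


def ordinal_blr(
    scores: Sequence[float], y: Sequence[bool], ci_level: float = 0.95
) -> tuple[float, float, tuple[float, float], float]:
    """Logistic regression of truth on an ordinal score as a linear term.

    Returns (coefficient, per-point OR, OR CI, Wald p): the association of
    each one-point score increase with the odds of pathologic EPE.
    """
    import statsmodels.api as sm

    x = np.asarray(scores, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("y must contain both classes")
    if len(np.unique(x)) < 2:
        raise ValueError("score is constant; association undefined")
    fit = sm.Logit(yv, sm.add_constant(x)).fit(disp=False)
    coef = float(fit.params[1])
    lo, hi = fit.conf_int(alpha=1 - ci_level)[1]
    return coef, math.exp(coef), (math.exp(lo), math.exp(hi)), float(fit.pvalues[1])


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for association in the 2x2 table."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


_EXACT_MAX_N = 12


def _mw_u(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses scipy's exact distribution when the combined sample is small
    (n <= 12) and untied, a full permutation enumeration when small but
    tied, and the tie-corrected normal approximation otherwise.  Returns
    (U of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n = a.size + b.size
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n
    if n <= _EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if n <= _EXACT_MAX_N:
        # full enumeration over which pooled positions form group A;
        # two-sided p = 2 * min(tail probs), as in randomization tests
        ranks = stats.rankdata(pooled)
        u_obs = _mw_u(ranks[: a.size], a.size)
        us = np.array([
            _mw_u(ranks[list(idx)], a.size)
            for idx in combinations(range(n), a.size)
        ])
        p_le = np.mean(us <= u_obs)
        p_ge = np.mean(us >= u_obs)
        return u_obs, float(min(1.0, 2 * min(p_le, p_ge)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
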