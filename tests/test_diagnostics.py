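"""2x2 accuracy statistics, odds ratios, logistic equivalence, rank tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mepescore.diagnostics import (
    NOT_DETERMINED,
    ContingencyTable,
    build_contingency,
    diagnostic_summary,
    fisher_exact,
    mann_whitney,
    odds_ratio_2x2,
    proportion_ci,
    univariate_blr,
)


def table_to_vectors(t: ContingencyTable):
    pred = [1] * t.tp + [1] * t.fp + [0] * t.fn + [0] * t.tn
    tru = [1] * t.tp + [0] * t.fp + [1] * t.fn + [0] * t.tn
    return pred, tru


# --- contingency construction ------------------------------------------------

def test_build_contingency_trivial():
    t = build_contingency([1, 1, 0, 0], [1, 1, 0, 0])
    assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 2)


def test_build_contingency_reconstructs_interface_table():
    pred, tru = table_to_vectors(ContingencyTable(23, 8, 22, 47))
    t = build_contingency(pred, tru)
    assert (t.tp, t.fp, t.fn, t.tn) == (23, 8, 22, 47)
    assert t.n == 100


def test_build_contingency_conserves_counts(rng):
    pred = rng.integers(0, 2, 50).astype(bool)
    tru = rng.integers(0, 2, 50).astype(bool)
    assert build_contingency(pred, tru).n == 50


def test_build_contingency_length_mismatch():
    with pytest.raises(ValueError, match="length mismatch"):
        build_contingency([1, 0], [1])


# --- diagnostic summary -------------------------------------------------------

def test_interface_sensitivity_and_wald_ci():
    s = diagnostic_summary(ContingencyTable(23, 8, 22, 47))
    assert s.sensitivity.estimate == pytest.approx(23 / 45)
    assert round(s.sensitivity.lower, 3) == 0.365
    assert round(s.sensitivity.upper, 2) == 0.66


def test_perfect_table_all_statistics_one_and_clipped():
    s = diagnostic_summary(ContingencyTable(7, 0, 0, 9))
    for stat in (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy):
        assert stat.estimate == 1.0
        assert stat.upper == 1.0
        assert stat.lower <= 1.0


def test_nvb_asymmetry_table_rational_values():
    s = diagnostic_summary(ContingencyTable(11, 2, 34, 53))
    assert s.ppv.estimate == pytest.approx(11 / 13)
    assert s.npv.estimate == pytest.approx(53 / 87)
    assert s.detection_rate.estimate == pytest.approx(11 / 13)


def test_zero_denominator_flagged_not_silent_zero():
    s = diagnostic_summary(ContingencyTable(0, 0, 3, 4))
    assert not s.ppv.defined
    assert not s.detection_rate.defined
    assert s.npv.defined


@settings(max_examples=200, derandomize=True, deadline=None)
@given(cells=st.tuples(*[st.integers(0, 60)] * 4))
def test_accuracy_identity(cells):
    """accuracy = prevalence*Se + (1-prevalence)*Sp, whenever all defined."""
    tp, fp, fn, tn = cells
    t = ContingencyTable(tp, fp, fn, tn)
    if t.n == 0 or t.n_pos == 0 or t.n_neg == 0:
        return
    s = diagnostic_summary(t)
    prev = t.n_pos / t.n
    assert s.accuracy.estimate == pytest.approx(
        prev * s.sensitivity.estimate + (1 - prev) * s.specificity.estimate
    )


@pytest.mark.parametrize("m", [100, 10_000, 1_000_000])
def test_wald_width_shrinks(m):
    k = int(0.3 * m)
    ci = proportion_ci(k, m)
    assert (ci.upper - ci.lower) == pytest.approx(
        2 * 1.959964 * math.sqrt(0.3 * 0.7 / m), rel=1e-3
    )


def test_wilson_and_clopper_pearson_options():
    wald = proportion_ci(1, 10, method="wald")
    wilson = proportion_ci(1, 10, method="wilson")
    cp = proportion_ci(1, 10, method="clopper-pearson")
    assert wald.lower == 0.0  # clipped
    assert 0 < wilson.lower < wilson.upper < 1
    assert 0 < cp.lower < cp.upper < 1


# --- odds ratios --------------------------------------------------------------

def test_or_interface_table_ci_matches_printed():
    orr, (lo, hi) = odds_ratio_2x2(ContingencyTable(23, 8, 22, 47))
    assert orr == pytest.approx(23 * 47 / (8 * 22))
    assert round(lo, 1) == 2.4
    assert round(hi) == 16


def test_or_zero_cell_not_determined():
    assert odds_ratio_2x2(ContingencyTable(9, 0, 36, 55)) == NOT_DETERMINED
    orr, _ = odds_ratio_2x2(ContingencyTable(9, 0, 36, 55), haldane=True)
    assert orr > 0


def test_or_symmetric_table_is_one():
    orr, _ = odds_ratio_2x2(ContingencyTable(6, 6, 6, 6))
    assert orr == pytest.approx(1.0)


def test_blr_matches_cross_product_on_interface_table():
    t = ContingencyTable(23, 8, 22, 47)
    pred, tru = table_to_vectors(t)
    res = univariate_blr(pred, tru)
    assert res.converged
    assert res.odds_ratio == pytest.approx(23 * 47 / (8 * 22), rel=1e-8)


def test_blr_nvb_table_ci_matches_printed_lower():
    # per-table Wald CI of the logistic OR; lower end reproduces the print
    _, (lo, hi) = odds_ratio_2x2(ContingencyTable(11, 2, 34, 53))
    assert round(lo, 1) == 1.8
    assert hi == pytest.approx(41.1, abs=0.1)


def test_blr_degenerate_designs_flagged():
    res = univariate_blr([1, 1, 1, 1], [1, 0, 1, 0])
    assert not res.converged and res.odds_ratio == NOT_DETERMINED
    sep = univariate_blr([1, 1, 0, 0], [1, 1, 0, 0])
    assert not sep.converged
    with pytest.raises(ValueError, match="both classes"):
        univariate_blr([1, 0, 1, 0], [1, 1, 1, 1])


# --- Fisher and Mann-Whitney ---------------------------------------------------

def _fisher_enumeration(t: ContingencyTable) -> float:
    """Hypergeometric enumeration over tables with the observed margins."""
    row1, col1, n = t.tp + t.fp, t.tp + t.fn, t.n
    dist = stats.hypergeom(n, col1, row1)
    p_obs = dist.pmf(t.tp)
    return sum(
        dist.pmf(k)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if dist.pmf(k) <= p_obs * (1 + 1e-9)
    )


@pytest.mark.parametrize("cells", [(5, 5, 5, 5), (10, 0, 0, 10), (45, 52, 0, 3),
                                   (3, 9, 7, 2), (1, 4, 6, 2)])
def test_fisher_exact_matches_enumeration(cells):
    t = ContingencyTable(*cells)
    assert fisher_exact(t) == pytest.approx(_fisher_enumeration(t), rel=1e-9)


def test_fisher_no_association_p_one():
    assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)


def test_mann_whitney_trivial_cases():
    _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert p > 0.9
    u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mann_whitney_tied_small_sample_matches_permutation_oracle(rng):
    a = rng.integers(0, 4, size=5).astype(float)
    b = rng.integers(1, 5, size=6).astype(float)
    u_obs, p = mann_whitney(a, b)

    # independent oracle: full enumeration of group assignments
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - len(a) * (len(a) + 1) / 2

    us = np.array([u_of(idx) for idx in combinations(range(11), 5)])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    expected = min(1.0, 2 * min(p_le, p_ge))
    assert p == pytest.approx(expected, rel=1e-12)


def test_mann_whitney_untied_small_sample_matches_scipy_exact():
    a, b = [1.0, 4.0, 7.0], [2.0, 3.0, 9.0, 11.0]
    u, p = mann_whitney(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert (u, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))
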