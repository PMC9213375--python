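"""ROC construction, AUC oracles, DeLong comparisons, threshold selection."""

import numpy as np
import pytest
from scipy import stats

from mepescore.roc import (
    RocAnalysis,
    OperatingPoint,
    compare_auc_paired,
    compare_auc_unpaired,
    roc_curve,
    select_threshold,
)
from mepescore.roc import _placements  # independent checks reach the internals


def pair_count_auc(scores, truths):
    """All-pairs concordance oracle: P(s+ > s-) + P(tie)/2."""
    s = np.asarray(scores, float)
    t = np.asarray(truths, bool)
    pos, neg = s[t], s[~t]
    wins = sum(np.sum(x > neg) + 0.5 * np.sum(x == neg) for x in pos)
    return wins / (pos.size * neg.size)


def trapezoid_auc(curve: RocAnalysis):
    """Geometric oracle: trapezoid over the ROC polyline incl. the (1,1) end.

    Operating points run from the lowest threshold (near (1,1)) to the
    highest (exactly (0,0), nothing called positive); prepending the
    all-positive corner closes the polyline.
    """
    pts = [(1.0, 1.0)] + [
        (1 - p.specificity, p.sensitivity) for p in curve.operating_points
    ]
    fpr, tpr = zip(*pts[::-1])
    return float(np.trapezoid(tpr, fpr))


def test_scores_equal_truth_gives_auc_one():
    truths = [0, 1, 0, 1, 1, 0]
    curve = roc_curve(truths, truths)
    assert curve.auc == 1.0
    assert curve.auc_ci == (1.0, 1.0) or curve.auc_ci[1] == 1.0


def test_independent_scores_give_auc_half(rng):
    scores = rng.integers(1, 6, 4000)
    truths = rng.uniform(size=4000) < 0.4
    assert roc_curve(scores, truths).auc == pytest.approx(0.5, abs=0.03)


def test_single_class_error():
    with pytest.raises(ValueError, match="truth-negative"):
        roc_curve([1, 2, 3], [True, True, True])
    with pytest.raises(ValueError, match="truth-positive"):
        roc_curve([1, 2, 3], [False, False, False])


def test_auc_equals_pair_counting_and_trapezoid(rng):
    for _ in range(25):
        n = int(rng.integers(10, 40))
        scores = rng.integers(1, 6, n)
        truths = rng.uniform(size=n) < 0.5
        if truths.all() or not truths.any():
            continue
        curve = roc_curve(scores, truths)
        assert curve.auc == pytest.approx(pair_count_auc(scores, truths), abs=1e-12)
        assert curve.auc == pytest.approx(trapezoid_auc(curve), abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.integers(1, 6, 300)
    truths = rng.uniform(size=300) < 0.45
    assert roc_curve(scores, truths).auc == pytest.approx(
        roc_auc_score(truths, scores), abs=1e-12
    )


def test_se_nonincreasing_sp_nondecreasing_in_threshold(rng):
    for _ in range(10):
        scores = rng.integers(1, 8, 200)
        truths = rng.uniform(size=200) < 0.5
        curve = roc_curve(scores, truths)
        se = [p.sensitivity for p in curve.operating_points]
        sp = [p.specificity for p in curve.operating_points]
        assert all(a >= b for a, b in zip(se, se[1:]))
        assert all(a <= b for a, b in zip(sp, sp[1:]))


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.integers(1, 6, 150).astype(float)
    truths = rng.uniform(size=150) < 0.5
    base = roc_curve(scores, truths).auc
    assert roc_curve(scores**3 + 2, truths).auc == pytest.approx(base, abs=1e-12)


# --- threshold selection ------------------------------------------------------

def test_dominating_point_selected_by_all_three():
    points = (
        OperatingPoint(1, 0.5, 0.5),
        OperatingPoint(2, 0.9, 0.9),
        OperatingPoint(3, 0.2, 0.95),
    )
    curve = RocAnalysis(points, 0.9, (0.8, 1.0), 0.05, 10, 10)
    sel = select_threshold(curve)
    assert sel.agreed
    assert sel.selected == 2
    assert sel.harmonic_mean_threshold == sel.corner_threshold == 2


def test_youden_maximizer_matches_enumeration(rng):
    scores = rng.integers(1, 6, 120)
    truths = rng.uniform(size=120) < 0.45
    curve = roc_curve(scores, truths)
    sel = select_threshold(curve)
    js = {p.threshold: p.sensitivity + p.specificity - 1
          for p in curve.operating_points}
    best = max(js.values())
    assert js[sel.youden_threshold] == pytest.approx(best)
    # selected is always the Youden maximizer (tie-break rule)
    assert sel.selected == sel.youden_threshold


def test_degenerate_curve_rejected():
    curve = RocAnalysis((OperatingPoint(1, 1, 1),), 1.0, (1, 1), 0.0, 5, 5)
    with pytest.raises(ValueError, match="operating points"):
        select_threshold(curve)


# --- paired / unpaired comparison ---------------------------------------------

def test_paired_identical_scores_delta_zero_p_one(rng):
    scores = rng.integers(1, 6, 60)
    truths = rng.uniform(size=60) < 0.5
    delta, p = compare_auc_paired(scores, scores, truths)
    assert delta == 0.0 and p == 1.0


def test_paired_antisymmetry(rng):
    s1 = rng.integers(1, 6, 80)
    s2 = rng.integers(1, 6, 80)
    truths = rng.uniform(size=80) < 0.5
    d12, p12 = compare_auc_paired(s1, s2, truths)
    d21, p21 = compare_auc_paired(s2, s1, truths)
    assert d12 == pytest.approx(-d21)
    assert p12 == pytest.approx(p21)


def test_paired_monotone_transform_delta_zero(rng):
    s1 = rng.integers(1, 6, 50).astype(float)
    truths = rng.uniform(size=50) < 0.5
    delta, _ = compare_auc_paired(s1, 2 * s1 + 1, truths)
    assert delta == pytest.approx(0.0, abs=1e-12)


def test_delong_variance_close_to_bootstrap(rng):
    """DeLong variance of delta-AUC vs a 10,000-rep patient bootstrap (n=20)."""
    n = 20
    truths = np.array([True] * 9 + [False] * 11)
    s1 = rng.integers(1, 6, n).astype(float) + truths * 1.5
    s2 = rng.integers(1, 6, n).astype(float) + truths * 0.5

    t = truths
    v10_1, v01_1 = _placements(s1[t], s1[~t])
    v10_2, v01_2 = _placements(s2[t], s2[~t])
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / t.sum() + s01 / (~t).sum()
    delong_var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]

    deltas = []
    for _ in range(10_000):
        idx = rng.integers(0, n, n)
        tt = truths[idx]
        if tt.all() or not tt.any():
            continue
        d = pair_count_auc(s1[idx], tt) - pair_count_auc(s2[idx], tt)
        deltas.append(d)
    boot_var = float(np.var(deltas, ddof=1))
    assert delong_var == pytest.approx(boot_var, rel=0.15)


def test_unpaired_identical_curves_p_one(rng):
    scores = rng.integers(1, 6, 100)
    truths = rng.uniform(size=100) < 0.5
    curve = roc_curve(scores, truths)
    assert compare_auc_unpaired(curve, curve) == 1.0


def test_unpaired_extreme_separation():
    rng = np.random.default_rng(7)
    truths = np.array([True] * 30 + [False] * 30)
    perfect = roc_curve(truths.astype(int), truths)
    noise = roc_curve(rng.integers(1, 6, 60), truths)
    assert compare_auc_unpaired(perfect, noise) < 0.01


def test_unpaired_null_p_uniform_over_replicates(rng):
    """Random subgroup splits of one cohort: p should be ~Uniform(0,1)."""
    ps = []
    for _ in range(200):
        scores = rng.integers(1, 6, 160)
        truths = rng.uniform(size=160) < 0.45
        half = rng.permutation(160) < 80
        try:
            ca = roc_curve(scores[half], truths[half])
            cb = roc_curve(scores[~half], truths[~half])
        except ValueError:
            continue
        ps.append(compare_auc_unpaired(ca, cb))
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_paired_length_mismatch():
    with pytest.raises(ValueError):
        compare_auc_paired([1, 2], [1, 2, 3], [True, False])
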