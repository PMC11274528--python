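"""Concordance, Bland–Altman, cross-tabulation and ROC statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from gliogrowth import agreement_stats as ag
from oracles import (auc_mann_whitney, bland_altman_decimal, ccc_decimal,
                     crosstab_by_counting)


FIXTURE_X = [31.2, 28.7, 35.1, 40.6, 25.3, 33.8, 29.9, 38.2, 27.4, 36.5]
FIXTURE_Y = [30.8, 29.5, 34.2, 41.9, 24.7, 35.0, 29.1, 37.0, 28.2, 35.1]


# ---------------------------------------------------------------------------
# Lin's CCC


def test_ccc_perfect_concordance():
    x = np.array(FIXTURE_X)
    assert ag.lin_ccc(x, x)[0] == pytest.approx(1.0, rel=1e-12)


def test_ccc_penalizes_constant_shift():
    x = np.array(FIXTURE_X)
    ccc, _ = ag.lin_ccc(x, x + 5.0)
    r, _ = ag.pearson_r(x, x + 5.0)
    assert r == pytest.approx(1.0, rel=1e-12)
    assert ccc < 1.0


def test_ccc_matches_decimal_formula_oracle():
    ccc, _ = ag.lin_ccc(FIXTURE_X, FIXTURE_Y)
    assert ccc == pytest.approx(ccc_decimal(FIXTURE_X, FIXTURE_Y), abs=1e-12)


def test_ccc_zero_variance_rejected():
    with pytest.raises(ValueError):
        ag.lin_ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


@settings(deadline=None, max_examples=40)
@given(st.lists(st.floats(-50, 50), min_size=4, max_size=25),
       st.integers(0, 2 ** 31 - 1))
def test_ccc_magnitude_bounded_by_pearson(xs, seed):
    x = np.asarray(xs)
    rng = np.random.default_rng(seed)
    y = x * rng.uniform(0.5, 2.0) + rng.normal(0, 1.0, len(x))
    if np.var(x) == 0 or np.var(y) == 0:
        return
    ccc, _ = ag.lin_ccc(x, y)
    r, _ = ag.pearson_r(x, y)
    assert abs(ccc) <= abs(r) + 1e-12
    assert abs(r) <= 1 + 1e-12


# ---------------------------------------------------------------------------
# Bland–Altman


def test_bland_altman_identical_series():
    x = np.array(FIXTURE_X)
    assert ag.bland_altman(x, x) == (0.0, 0.0, 0.0)


def test_bland_altman_reproduces_reported_interval_shape():
    """Differences with mean 3.7 and sd 12.9 give limits ~(-21.6, +29.0),
    the magnitude printed for 3D-vs-volume agreement studies."""
    rng = np.random.default_rng(42)
    d = rng.normal(0.0, 1.0, 60)
    d = (d - d.mean()) / d.std(ddof=1) * 12.9 + 3.7
    y = rng.uniform(5, 60, 60)
    mean, lo, hi = ag.bland_altman(y + d, y)
    assert mean == pytest.approx(3.7, abs=1e-9)
    assert lo == pytest.approx(3.7 - 1.96 * 12.9, abs=1e-9)  # -21.58
    assert hi == pytest.approx(3.7 + 1.96 * 12.9, abs=1e-9)  # +28.98


def test_bland_altman_matches_decimal_oracle():
    got = ag.bland_altman(FIXTURE_X, FIXTURE_Y)
    want = bland_altman_decimal(FIXTURE_X, FIXTURE_Y)
    assert got == pytest.approx(want, abs=1e-12)


def test_bland_altman_antisymmetry():
    m1, l1, h1 = ag.bland_altman(FIXTURE_X, FIXTURE_Y)
    m2, l2, h2 = ag.bland_altman(FIXTURE_Y, FIXTURE_X)
    assert (m2, l2, h2) == pytest.approx((-m1, -h1, -l1), abs=1e-12)


# ---------------------------------------------------------------------------
# cross-tabulation


def test_crosstab_perfect_predictor():
    truth = np.array([True] * 6 + [False] * 7)
    rep = ag.crosstab_metrics(truth, truth)
    assert rep.sensitivity == 100.0
    assert rep.specificity == 100.0


def test_crosstab_printed_diagnostics_fixture():
    """TP=73, FN=29, TN=121, FP=7 at n=230: sens 71.6%, spec 94.5% —
    the sensitivity/specificity geometry of a highly specific 1D method."""
    pred = [True] * 73 + [False] * 29 + [False] * 121 + [True] * 7
    truth = [True] * 102 + [False] * 128
    rep = ag.crosstab_metrics(pred, truth)
    oracle = crosstab_by_counting(pred, truth)
    assert rep.n == 230
    assert rep.sensitivity == pytest.approx(oracle["sens"], abs=1e-12)
    assert rep.specificity == pytest.approx(oracle["spec"], abs=1e-12)
    assert round(rep.sensitivity, 1) == 71.6
    assert round(rep.specificity, 1) == 94.5
    assert rep.lr_pos == pytest.approx(rep.sensitivity
                                       / (100 - rep.specificity), rel=1e-12)


def test_crosstab_degenerate_predictor():
    truth = np.array([True] * 5 + [False] * 5)
    rep = ag.crosstab_metrics(np.zeros(10, dtype=bool), truth)
    assert rep.sensitivity == 0.0
    assert rep.specificity == 100.0
    assert rep.ppv is None  # no positive predictions


def test_crosstab_absent_truth_class_reports_none():
    truth = np.zeros(8, dtype=bool)
    rep = ag.crosstab_metrics(np.array([True] * 3 + [False] * 5), truth)
    assert rep.sensitivity is None
    assert rep.specificity is not None


def test_crosstab_bayes_identity():
    """PPV must equal sens*prev / (sens*prev + (1-spec)*(1-prev))."""
    rng = np.random.default_rng(3)
    truth = rng.uniform(size=200) < 0.4
    pred = truth ^ (rng.uniform(size=200) < 0.2)
    rep = ag.crosstab_metrics(pred, truth)
    prev = truth.mean()
    sens = rep.sensitivity / 100
    spec = rep.specificity / 100
    ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
    assert rep.ppv == pytest.approx(100 * ppv, abs=1e-9)
    npv = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev)
    assert rep.npv == pytest.approx(100 * npv, abs=1e-9)


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    changes = np.array([5.0, 8.0, 12.0, 45.0, 52.0, 61.0])
    truth = changes > 20
    auc, thr, sens, spec = ag.roc_optimal_threshold(changes, truth)
    assert auc == pytest.approx(1.0)
    assert 12.0 <= thr < 45.0
    assert sens == 100.0 and spec == 100.0


def test_roc_no_signal_limit():
    rng = np.random.default_rng(7)
    changes = rng.normal(30, 20, 800)
    truth = rng.permutation(np.array([True, False] * 400))
    auc, *_ = ag.roc_optimal_threshold(changes, truth)
    assert auc == pytest.approx(0.5, abs=0.06)


def test_roc_auc_equals_mann_whitney_u_fixture():
    rng = np.random.default_rng(11)
    changes = np.round(rng.normal(30, 15, 20), 1)
    truth = rng.uniform(size=20) < 0.5
    truth[:2] = [True, False]  # both classes present
    auc, *_ = ag.roc_optimal_threshold(changes, truth)
    assert auc == pytest.approx(auc_mann_whitney(changes, truth), abs=1e-12)
    u = mannwhitneyu(changes[truth], changes[~truth]).statistic
    assert auc == pytest.approx(u / (truth.sum() * (~truth).sum()),
                                abs=1e-12)


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2 ** 31 - 1))
def test_roc_auc_mann_whitney_identity_randomized(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    changes = np.round(rng.normal(30, 15, n), 0)  # coarse: force ties
    truth = rng.uniform(size=n) < 0.5
    truth[0], truth[1] = True, False
    auc, *_ = ag.roc_optimal_threshold(changes, truth)
    assert auc == pytest.approx(auc_mann_whitney(changes, truth), abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        ag.roc_optimal_threshold([1.0, 2.0], [True, True])


def test_roc_youden_tie_prefers_higher_specificity():
    changes = np.array([10.0, 20.0, 30.0, 40.0])
    truth = np.array([False, False, True, True])
    # cuts 20 and 25-ish both give J=1; the reported cutoff is the largest
    auc, thr, sens, spec = ag.roc_optimal_threshold(changes, truth)
    assert thr == 20.0
    assert auc == 1.0


# ---------------------------------------------------------------------------
# subgroup and sweep


def test_subgroup_identical_pairs_have_unit_ccc():
    rng = np.random.default_rng(5)
    vde = rng.normal(3, 2, 40)
    mtd = rng.uniform(20, 50, 40)
    out = ag.subgroup_concordance(mtd, vde, vde)
    for grp in ("small", "large"):
        assert out[grp]["lin_ccc"] == pytest.approx(1.0)
        assert out[grp]["mean_diff"] == pytest.approx(0.0, abs=1e-12)


def test_subgroup_small_tumor_noise_degrades_concordance():
    """Measurement noise inversely proportional to MTD makes the small-MTD
    subgroup less concordant — the residue effect in miniature."""
    rng = np.random.default_rng(6)
    mtd = rng.uniform(15, 60, 400)
    vde_v = rng.normal(3, 2, 400)
    vde_3d = vde_v + rng.normal(0, 60.0 / mtd)
    out = ag.subgroup_concordance(mtd, vde_v, vde_3d)
    assert out["small"]["lin_ccc"] < out["large"]["lin_ccc"]


def test_subgroup_degenerate_cut_flags_empty():
    out = ag.subgroup_concordance([20.0, 25.0], [1.0, 2.0], [1.0, 2.0],
                                  cut_mm=100.0)
    assert out["large"]["empty"]
    assert out["large"]["lin_ccc"] is None


def test_sweep_zero_cutoff_is_full_sample():
    rng = np.random.default_rng(8)
    dm = rng.uniform(0, 8, 50)
    v = rng.normal(3, 2, 50)
    w = v + rng.normal(0, 1, 50)
    curve = ag.vde_concordance_sweep(dm, v, w, grid=[0.0, 100.0])
    assert curve[0]["fraction_retained"] == 1.0
    assert curve[0]["lin_ccc"] == pytest.approx(ag.lin_ccc(w, v)[0])
    assert curve[1]["fraction_retained"] == 0.0
    assert curve[1]["lin_ccc"] is None


def test_sweep_concordance_improves_when_small_changes_are_noise_dominated():
    """When the VDE error scales like 1/ΔMTD (a fixed MTD measurement
    error matters most for small changes), excluding small-ΔMTD windows
    raises the concordance above the full-sample value — the mechanism
    behind imposing a minimal ΔMTD before trusting the VDE."""
    rng = np.random.default_rng(9)
    n = 500
    dm = rng.uniform(0.2, 12, n)
    vde_v = dm * 1.1  # signal scales with the MTD change
    vde_3d = vde_v + rng.normal(0, 1.5, n) * 3.0 / dm
    grid = [0.0, 2.0, 4.0, 6.0]
    curve = ag.vde_concordance_sweep(dm, vde_v, vde_3d, grid=grid)
    cccs = [pt["lin_ccc"] for pt in curve]
    fracs = [pt["fraction_retained"] for pt in curve]
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))
    assert all(c > cccs[0] for c in cccs[1:])
    assert cccs[1] > cccs[0] + 0.05
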