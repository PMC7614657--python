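"""Statistics layer: Hill fits, gates, robust fits, bootstrap, t-tests."""

import numpy as np
import pytest
from scipy import stats as sps

from rtqibc import (
    DoseResponseFit,
    GateDirection,
    bootstrap_ci,
    binned_summary,
    derive_gate,
    fit_hill,
    fold_inhibition,
    hill_curve,
    normalize_values,
    robust_line_through_origin,
    sample_dose_response,
    stratified_dose_response,
    subsample_equal,
    t_test,
    trim_outliers,
)
from rtqibc.stats import GateThreshold


# ---------------------------------------------------------------- Hill model
def test_hill_curve_closed_form_values():
    # midpoint, limits, and a hand-evaluated point of the printed formula
    assert hill_curve(10.2, 22, 1, 10.2, 4.2) == pytest.approx((22 + 1) / 2)
    assert hill_curve(1e-9, 22, 1, 10.2, 4.2) == pytest.approx(22, abs=1e-6)
    assert hill_curve(1e9, 22, 1, 10.2, 4.2) == pytest.approx(1, abs=1e-4)
    # x = 2*IC50: EdU = 22 - 21/(1 + 0.5^4.2), evaluated independently
    expected = 22 - 21 / (1 + 0.5**4.2)
    assert hill_curve(20.4, 22, 1, 10.2, 4.2) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(2.0836, abs=5e-4)


@pytest.mark.parametrize("params", [
    (22.0, 1.0, 10.2, 4.2),      # siCtrl-like
    (22.0, 22 / 23, 7.7, 1.8),   # siGeminin-like
    (22.0, 22 / 25.7, 5.49, 4.2),  # DMSO-like
    (10.0, 2.0, 3.0, 0.7),
])
def test_fit_hill_zero_noise_exact(params):
    """Noise-free data must recover generating parameters to >= 4 sig digits."""
    gen = DoseResponseFit(*params)
    df = sample_dose_response(gen, 1000, 0.0, seed=3)
    fit = fit_hill(df.ndcdt1, df.edu, edu_max=gen.edu_max)
    assert fit.ic50 == pytest.approx(gen.ic50, rel=1e-4)
    assert fit.n_hill == pytest.approx(gen.n_hill, rel=1e-4)
    assert fit.edu_min == pytest.approx(gen.edu_min, rel=1e-3)


def test_fit_hill_fixed_edu_min():
    gen = DoseResponseFit(22.0, 1.0, 10.2, 4.2)
    df = sample_dose_response(gen, 500, 0.0, seed=4)
    fit = fit_hill(df.ndcdt1, df.edu, edu_max=22.0, fix_edu_min=1.0)
    assert not fit.fitted_edu_min
    assert fit.ic50 == pytest.approx(10.2, rel=1e-5)


def test_fit_hill_degenerate_no_inhibition():
    rng = np.random.default_rng(0)
    x = np.exp(rng.uniform(np.log(0.5), np.log(40), 500))
    y = np.full(500, 22.0)
    with pytest.raises(ValueError, match="degenerate"):
        fit_hill(x, y, edu_max=22.0)


def test_fit_hill_objective_not_worse_than_grid_oracle():
    """The optimizer's SSE must never exceed a brute-force grid search's
    (log-spaced IC50 x n grid, EdU_min profiled by least squares)."""
    gen = DoseResponseFit(22.0, 1.0, 10.2, 4.2)
    df = sample_dose_response(gen, 500, 0.3, seed=7)
    x, y = df.ndcdt1.to_numpy(), df.edu.to_numpy()
    emax = 22.0
    best = np.inf
    for ic50 in np.geomspace(1.0, 40.0, 40):
        for n in np.geomspace(0.3, 8.0, 40):
            # model: y = emax - (emax - emin)*g, linear in emin
            g = 1.0 / (1.0 + (ic50 / x) ** n)
            # y = emax(1-g) + emin*g  ->  emin = sum(g*(y - emax(1-g)))/sum(g^2)
            emin = np.dot(g, y - emax * (1 - g)) / np.dot(g, g)
            emin = min(max(emin, 0.0), emax)
            sse = np.sum((emax - (emax - emin) * g - y) ** 2)
            best = min(best, sse)
    fit = fit_hill(x, y, edu_max=emax)
    assert fit.rss <= best + 1e-9


def test_fold_inhibition():
    assert fold_inhibition(DoseResponseFit(22.0, 1.0, 10.0, 4.0)) == pytest.approx(22.0)
    assert fold_inhibition(DoseResponseFit(10.0, 10.0, 1.0, 1.0)) == pytest.approx(1.0)
    # matches the brute-force extrema of the fitted curve over x
    fit = DoseResponseFit(18.0, 1.5, 5.0, 2.0)
    x = np.geomspace(1e-6, 1e6, 20001)
    curve = fit.predict(x)
    assert fold_inhibition(fit) == pytest.approx(curve.max() / curve.min(), rel=1e-3)
    with pytest.raises(ValueError):
        fold_inhibition(DoseResponseFit(22.0, 0.0, 10.0, 4.0))


def test_dose_response_invariants_and_errors():
    gen = DoseResponseFit(22.0, 1.0, 10.2, 4.2)
    a = sample_dose_response(gen, 100, 0.2, seed=5)
    b = sample_dose_response(gen, 100, 0.2, seed=5)
    assert a.equals(b)  # seeded determinism
    assert (a.edu >= 0).all()
    with pytest.raises(ValueError):
        sample_dose_response(gen, 5, 0.1)
    with pytest.raises(ValueError):
        sample_dose_response(gen, 100, -0.1)
    # noise mean ~1: average EdU at low expression approaches edu_max
    big = sample_dose_response(gen, 50000, 0.3, expression_range=(0.01, 0.02), seed=6)
    assert big.edu.mean() == pytest.approx(22.0, rel=0.02)


# ---------------------------------------------------------------- gating
def test_derive_gate_percentile_and_application():
    vals = np.arange(1.0, 1001.0)
    gate = derive_gate(vals, percentile=99)
    assert 990 <= gate.value <= 991
    marked = gate.is_positive(vals).mean()
    assert marked == pytest.approx(0.01, abs=0.005)
    const = derive_gate(np.full(100, 7.0), percentile=99)
    assert const.value == 7.0
    with pytest.raises(ValueError):
        derive_gate(np.arange(10.0))
    below = GateThreshold(5.0, 99, direction=GateDirection.BELOW_IS_POSITIVE)
    assert below.is_positive([1.0, 10.0]).tolist() == [True, False]


# ---------------------------------------------------------------- stratified
def test_stratified_dose_response_recovers_linear_ic50_trend():
    rng = np.random.default_rng(2)
    n = 24000
    g = rng.uniform(0.0, 10.0, n)             # stratification level (geminin)
    a_true, b_true = 3.0, 0.8
    ic50 = a_true + b_true * g
    x = np.exp(rng.uniform(np.log(0.5), np.log(40), n))
    y = (22 - (22 - 1) / (1 + (ic50 / x) ** 3.0)) * rng.lognormal(0, 0.2, n)
    fits, table, trend = stratified_dose_response(
        x, y, g, n_bins=8, edu_max=22.0, min_cells_per_bin=660)
    assert len(table) == 8
    assert trend["slope"] == pytest.approx(b_true, rel=0.10)

    flat = stratified_dose_response(x, (22 - 21 / (1 + (5.0 / x) ** 3.0)),
                                    g, n_bins=6, edu_max=22.0, min_cells_per_bin=660)
    assert abs(flat[2]["slope"]) < 0.05
    with pytest.raises(ValueError):
        stratified_dose_response(x, y, g, n_bins=1, edu_max=22.0)


# ---------------------------------------------------------------- robust fit
def test_robust_line_exact_and_contaminated():
    x = np.linspace(1, 10, 50)
    assert robust_line_through_origin(x, 2 * x) == pytest.approx(2.0, abs=1e-9)
    rng = np.random.default_rng(3)
    y = 2 * x + rng.normal(0, 0.05, x.size)
    y[::10] += 30.0  # 10% gross outliers
    slope = robust_line_through_origin(x, y)
    ols = np.dot(x, y) / np.dot(x, x)
    assert abs(slope - 2.0) / 2.0 < 0.02
    assert abs(ols - 2.0) / 2.0 > 0.05
    with pytest.raises(ValueError):
        robust_line_through_origin(np.zeros(10), np.arange(10.0))


def test_robust_line_matches_statsmodels_rlm():
    """Cross-check the hand-rolled IRLS against statsmodels' Tukey biweight."""
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    x = np.linspace(0.5, 20, 200)
    y = 1.7 * x + rng.standard_t(3, x.size)
    ours = robust_line_through_origin(x, y, tuning=2.0)
    theirs = sm.RLM(y, x[:, None], M=sm.robust.norms.TukeyBiweight(c=2.0)).fit().params[0]
    assert ours == pytest.approx(theirs, rel=0.02)


# ---------------------------------------------------------------- bootstrap
def test_bootstrap_ci_constant_and_monotone_level():
    lo, hi = bootstrap_ci(np.full(20, 3.0), np.mean, seed=0)
    assert (lo, hi) == (3.0, 3.0)
    vals = np.random.default_rng(5).normal(0, 1, 300)
    lo95, hi95 = bootstrap_ci(vals, np.mean, level=0.95, seed=1)
    lo99, hi99 = bootstrap_ci(vals, np.mean, level=0.99, seed=1)
    assert lo99 <= lo95 and hi99 >= hi95


def test_bootstrap_coverage_near_nominal():
    """95% percentile interval for a normal mean should cover ~95% of the time."""
    rng = np.random.default_rng(6)
    cover = 0
    reps = 200
    for _ in range(reps):
        vals = rng.normal(0, 1, 250)
        lo, hi = bootstrap_ci(vals, np.mean, n_boot=1000, seed=rng)
        cover += lo <= 0 <= hi
    assert 0.92 <= cover / reps <= 0.98


# ---------------------------------------------------------------- summaries
def test_binned_summary_fraction_and_empty():
    gate = GateThreshold(10.0, 99)
    rng = np.random.default_rng(7)
    times = rng.uniform(0, 30, 400)
    values = np.full(400, 1.0)
    out = binned_summary(times, values, 3.0, "fraction_below_gate",
                        min_per_bin=10, gate=gate, seed=0)
    assert (out["estimate"] == 1.0).all()
    empty = binned_summary([], [], 3.0, "median", min_per_bin=1)
    assert len(empty) == 0


def test_binned_summary_degradation_half_time():
    """The fraction-degraded curve must cross 0.5 within one bin of the
    programmed decay half-time (gate at half the initial level)."""
    rng = np.random.default_rng(8)
    t = rng.uniform(0, 40, 4000)
    level = 100 * 2 ** (-t / 9.0) * rng.lognormal(0, 0.05, t.size)
    gate = GateThreshold(50.0, 99, direction=GateDirection.BELOW_IS_POSITIVE)
    out = binned_summary(t, level, 3.0, "fraction_below_gate",
                        min_per_bin=36, gate=gate, seed=0)
    crossing = out.loc[out["estimate"] >= 0.5, "t_center"].iloc[0]
    assert abs(crossing - 9.0) <= 3.0


def test_normalize_values_affine_consistency():
    v = np.array([1.0, 2.0, 5.0])
    assert normalize_values(v, g1_baseline=1.0, reference=2.0)[0] == 0.0
    a, b = 3.0, 7.0
    direct = normalize_values(a * v + b, g1_baseline=a * 1.0 + b, reference=a * 2.0)
    assert np.allclose(direct, a * (v - 1.0) / (a * 2.0))
    with pytest.raises(ValueError):
        normalize_values(v, 0.0, 0.0)


def test_trim_outliers_counts_and_contract():
    vals = np.arange(1000.0)
    out = trim_outliers(vals, 0.01)
    assert len(out) == 990
    again = trim_outliers(out, 0.01)
    assert len(out) - len(again) <= np.ceil(0.01 * len(out)) + 1
    both = trim_outliers(vals, 0.01, symmetric=True)
    assert len(both) == 980 and both.min() >= 9


def test_subsample_equal():
    groups = {"a": np.arange(100), "b": np.arange(40)}
    out = subsample_equal(groups, seed=0)
    assert len(out["a"]) == len(out["b"]) == 40
    assert len(np.unique(out["a"])) == 40  # without replacement
    same = subsample_equal({"a": np.arange(5), "b": np.arange(5)}, seed=0)
    assert sorted(same["a"]) == list(range(5))


def test_t_test_matches_hand_computation():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 6.0])
    t, p = t_test(a, b, "two_sample")
    ref = sps.ttest_ind(a, b)
    assert t == pytest.approx(ref.statistic, abs=1e-6)
    assert p == pytest.approx(ref.pvalue, abs=1e-6)
    # hand computation: pooled SE
    sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
    assert t == pytest.approx(t_hand, abs=1e-6)
    t1, p1 = t_test(a - 0.5, mode="one_sample", mu0=0.0)
    assert p1 == pytest.approx(sps.ttest_1samp(a - 0.5, 0.0).pvalue)
    with pytest.raises(ValueError):
        t_test(a, a, "paired")  # zero-variance differences
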