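"""Tri-phase fit stages: closed-form oracles, phase rules, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from triphase import FitConfig, SimConfig, fit_simulated
from triphase.errors import (
    DomainError,
    InsufficientDataError,
    InsufficientSpreadError,
    NonDecreasingResponseError,
)
from triphase.triphase_core import (
    PsiBin,
    SlowPhaseFit,
    breakpoints,
    classify_bins,
    fit_slow_phase,
    fit_thermal_rate,
    fit_triphase,
    relative_growth,
    select_slow_subset,
)


def make_series(hour, ler, temp, psi, after=None, rgra=None):
    df = pd.DataFrame(
        {
            "hour": hour,
            "ler_mm_h": ler,
            "temp_c": temp,
            "psi_log10": psi,
            "after_rewatering": after if after is not None else False,
        }
    )
    if rgra is not None:
        df["rgra"] = rgra
    return df


def bins_from_means(means, lo0=2.0):
    """Build a PsiBin ladder from consecutive quarter-bin means."""
    out = []
    thresholds = FitConfig()
    for k, m in enumerate(means):
        lo = lo0 + 0.25 * k
        if m is None:
            out.append(PsiBin(lo, lo + 0.25, float("nan"), 0, "empty"))
            continue
        phase = "normal" if m > 0.9 else "arrest" if m < 0.2 else "slow"
        out.append(PsiBin(lo, lo + 0.25, m, 5, phase))
    return out


class TestThermalRate:
    def test_exact_linearity(self):
        t = np.linspace(14, 26, 24)
        s = make_series(np.arange(24), 2.0 * t, t, 1.8)
        fit = fit_thermal_rate(s)
        assert fit.a == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 24

    def test_two_point_closed_form(self):
        """(T, LER) = (10, 0.5), (20, 1.1), plus a third point to satisfy
        the minimum-n rule at (30, 1.62): a = sum(T*L)/sum(T^2)."""
        t = np.array([10.0, 20.0, 30.0])
        y = np.array([0.5, 1.1, 1.62])
        s = make_series([0, 1, 2], y, t, 1.8)
        fit = fit_thermal_rate(s)
        assert fit.a == pytest.approx(np.sum(t * y) / np.sum(t * t), abs=1e-12)

    def test_agrees_with_grid_search(self, rng):
        """Oracle: direct minimisation of the through-origin squared error."""
        t = rng.uniform(14, 26, 10)
        y = 0.05 * t + rng.normal(0, 0.05, 10)
        s = make_series(np.arange(10), y, t, 1.8)
        fit = fit_thermal_rate(s)
        best = minimize(lambda a: np.sum((y - a[0] * t) ** 2), [0.1], tol=1e-14)
        assert fit.a == pytest.approx(best.x[0], abs=1e-8)

    def test_window_limits_points(self):
        s = make_series(np.arange(48), 1.0, 20.0, 1.8)
        assert fit_thermal_rate(s, window_h=24).n_points == 24

    def test_too_few_points_raises(self):
        s = make_series([0, 1], [1.0, 1.0], [20.0, 20.0], 1.8)
        with pytest.raises(InsufficientDataError):
            fit_thermal_rate(s)

    def test_zero_temperature_hours_excluded(self):
        s = make_series(np.arange(5), 1.0, [20, 20, 20, 0.0, -1.0], 1.8)
        assert fit_thermal_rate(s).n_points == 3


class TestRelativeGrowth:
    def test_normal_phase_rgra_is_one(self):
        t = np.linspace(15, 25, 24)
        fit = fit_thermal_rate(make_series(np.arange(24), 0.05 * t, t, 1.8))
        out = relative_growth(make_series(np.arange(24), 0.05 * t, t, 1.8), fit)
        assert np.allclose(out["rgra"], 1.0)

    def test_zero_ler_gives_zero(self):
        t = np.full(24, 20.0)
        fit = fit_thermal_rate(make_series(np.arange(24), 0.05 * t, t, 1.8))
        out = relative_growth(make_series(np.arange(24), 0.0, t, 1.8), fit)
        assert np.allclose(out["rgra"], 0.0)

    def test_direct_arithmetic(self):
        t = np.full(24, 20.0)
        fit_in = make_series(np.arange(24), 0.05 * t, t, 1.8)
        fit = fit_thermal_rate(fit_in)
        out = relative_growth(make_series(np.arange(24), 0.6, t, 1.8), fit)
        assert np.allclose(out["rgra"], 0.6 / (0.05 * 20.0))

    def test_nonpositive_a_rejected(self):
        fit = dataclasses.replace(
            fit_thermal_rate(make_series(np.arange(3), [1, 1, 1], [20, 21, 22], 1.8)),
            a=-0.1,
        )
        with pytest.raises(DomainError):
            relative_growth(make_series(np.arange(3), 1.0, 20.0, 1.8), fit)


class TestClassifyBins:
    def _series_with_bin_means(self, means):
        """Five hours per quarter bin, rgra equal to the target bin mean."""
        rows = []
        for k, m in enumerate(means):
            lo = 2.0 + 0.25 * k
            for j in range(5):
                rows.append((len(rows), m, 20.0, lo + 0.05 * j, m))
        h, r, t, p, g = zip(*[(a, b, c, d, e) for a, b, c, d, e in rows])
        return make_series(list(h), list(r), list(t), list(p), rgra=list(g))

    def test_all_normal(self):
        bins = classify_bins(self._series_with_bin_means([1.0, 1.0, 1.0]))
        assert [b.phase for b in bins if b.phase != "empty"] == ["normal"] * 3

    def test_rebound_rule_rescues_single_dip(self):
        """Means [1.0, 0.85, 0.96, 0.6, 0.1]: the 0.85 dip is followed by a
        normal bin, so it stays normal."""
        bins = classify_bins(self._series_with_bin_means([1.0, 0.85, 0.96, 0.6, 0.1]))
        assert [b.phase for b in bins if b.phase != "empty"] == [
            "normal", "normal", "normal", "slow", "arrest",
        ]

    def test_monotone_decline(self):
        bins = classify_bins(self._series_with_bin_means([1.0, 0.5, 0.15]))
        assert [b.phase for b in bins if b.phase != "empty"] == ["normal", "slow", "arrest"]

    def test_boundary_values_are_slow(self):
        bins = classify_bins(self._series_with_bin_means([0.9, 0.2]))
        assert [b.phase for b in bins if b.phase != "empty"] == ["slow", "slow"]

    def test_rebound_never_rescues_arrest(self):
        bins = classify_bins(self._series_with_bin_means([1.0, 0.1, 0.95]))
        assert [b.phase for b in bins if b.phase != "empty"] == ["normal", "arrest", "normal"]

    def test_bins_on_absolute_quarters(self):
        s = make_series([0, 1, 2], [1, 1, 1], 20.0, [2.13, 2.18, 2.21], rgra=[1, 1, 1])
        bins = classify_bins(s)
        assert bins[0].lo == pytest.approx(2.0)
        assert bins[0].hi == pytest.approx(2.25)

    def test_empty_series_raises(self):
        s = make_series([0], [1.0], 20.0, [np.nan], rgra=[np.nan])
        with pytest.raises(InsufficientDataError):
            classify_bins(s)


class TestSelectSlowSubset:
    def _series(self, psis, rgras):
        return make_series(range(len(psis)), rgras, 20.0, psis, rgra=rgras)

    def test_counts_slow_plus_retained_normal(self):
        """normal(2.00-2.25) x5, slow(2.25-2.50) x4, arrest(2.50-2.75) x6:
        5 + 4 = 9 points selected."""
        psis = [2.05 + 0.01 * j for j in range(5)] + \
               [2.30 + 0.01 * j for j in range(4)] + \
               [2.55 + 0.01 * j for j in range(6)]
        rgras = [1.0] * 5 + [0.5] * 4 + [0.1] * 6
        s = self._series(psis, rgras)
        subset = select_slow_subset(s, classify_bins(s))
        assert len(subset) == 9

    def test_all_normal_returns_none(self):
        s = self._series([2.05, 2.30, 2.55], [1.0, 1.0, 1.0])
        assert select_slow_subset(s, classify_bins(s)) is None

    def test_only_highest_normal_bin_retained(self):
        """Two disjoint normal runs: only the highest-psi normal bin's
        points are kept alongside the slow bins."""
        psis = [2.05, 2.30, 2.55, 2.80, 3.05]
        rgras = [1.0, 0.85, 1.0, 0.5, 0.3]  # 0.85 rescued by rebound
        s = self._series(psis, rgras)
        bins = classify_bins(s)
        subset = select_slow_subset(s, bins)
        # retained normal bin is 2.50-2.75; 2.05 and 2.30 are excluded
        assert set(np.round(subset["psi_log10"], 2)) == {2.55, 2.80, 3.05}

    def test_retention_can_be_disabled(self):
        psis = [2.05, 2.30, 2.35, 2.60, 2.65]
        rgras = [1.0, 0.6, 0.5, 0.4, 0.3]
        s = self._series(psis, rgras)
        bins = classify_bins(s)
        cfg = FitConfig(retain_last_normal_bin=False)
        subset = select_slow_subset(s, bins, cfg)
        assert 2.05 not in set(subset["psi_log10"])

    def test_arrest_is_terminal(self):
        """Points drier than the first arrest bin never re-enter, even if a
        later bin mean drifts above the arrest threshold."""
        psis = [2.05, 2.30, 2.55, 2.80, 3.05]
        rgras = [1.0, 0.5, 0.1, 0.3, 0.25]
        s = self._series(psis, rgras)
        subset = select_slow_subset(s, classify_bins(s))
        assert subset["psi_log10"].max() < 2.5


class TestSlowPhaseFit:
    def test_exact_line(self):
        pts = make_series([0, 1, 2], 0, 20.0, [2.0, 2.5, 3.0],
                          rgra=[1.0, 0.5, 0.0])
        fit = fit_slow_phase(pts)
        assert fit.i == pytest.approx(3.0, abs=1e-12)
        assert fit.c == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        """(2.5, 0.9), (3.0, 0.5), (3.5, 0.1): i = 2.9, c = -0.8."""
        pts = make_series([0, 1, 2], 0, 20.0, [2.5, 3.0, 3.5],
                          rgra=[0.9, 0.5, 0.1])
        fit = fit_slow_phase(pts)
        assert fit.i == pytest.approx(2.9, abs=1e-12)
        assert fit.c == pytest.approx(-0.8, abs=1e-12)

    def test_agrees_with_normal_equations(self, rng):
        x = rng.uniform(2.0, 3.5, 10)
        y = 3.0 - 1.1 * x + rng.normal(0, 0.05, 10)
        pts = make_series(range(10), 0, 20.0, x, rgra=y)
        fit = fit_slow_phase(pts)
        A = np.vstack([np.ones_like(x), x]).T
        i_hat, c_hat = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.i == pytest.approx(i_hat, abs=1e-10)
        assert fit.c == pytest.approx(c_hat, abs=1e-10)

    def test_positive_slope_rejected(self):
        pts = make_series([0, 1, 2], 0, 20.0, [2.0, 2.5, 3.0], rgra=[0.1, 0.5, 0.9])
        with pytest.raises(NonDecreasingResponseError):
            fit_slow_phase(pts)

    def test_degenerate_spread_rejected(self):
        pts = make_series([0, 1, 2], 0, 20.0, [2.0, 2.1, 2.2], rgra=[0.9, 0.5, 0.1])
        with pytest.raises(InsufficientSpreadError):
            fit_slow_phase(pts)


class TestBreakpoints:
    def test_unit_slope(self):
        up, lo = breakpoints(SlowPhaseFit(i=3.0, c=-1.0, r_squared=1.0, n_points=3))
        assert (up, lo) == (2.0, 3.0)

    def test_reference_tiller_values(self):
        """i = 3.4, c = -1.0 puts the slow and arrest points at 2.4 and 3.4
        log10 hPa — the single-tiller worked example."""
        up, lo = breakpoints(SlowPhaseFit(i=3.4, c=-1.0, r_squared=1.0, n_points=3))
        assert up == pytest.approx(2.4)
        assert lo == pytest.approx(3.4)

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(DomainError):
            breakpoints(SlowPhaseFit(i=3.0, c=0.0, r_squared=1.0, n_points=3))

    @given(
        i=st.floats(1.2, 6.0),
        c=st.floats(-3.0, -0.2),
    )
    @settings(deadline=None)
    def test_identities(self, i, c):
        """sigma_lower - sigma_upper = -1/c and sigma_upper = (1-i)/c."""
        fit = SlowPhaseFit(i=i, c=c, r_squared=1.0, n_points=3)
        up, lo = breakpoints(fit)
        assert lo - up == pytest.approx(-1.0 / c, rel=1e-12)
        assert up == pytest.approx((1.0 - i) / c, rel=1e-12)
        assert up < lo


class TestFullFit:
    def test_control_series_is_normal_throughout(self):
        """psi pinned well below the slow point: thermal fit only."""
        cfg = SimConfig(psi_timescale=1e12, rewater_time=None,
                        noise_sd_ler=0.0, n_replicates=1, duration=96.0)
        res = fit_simulated(cfg)[0]
        assert not res.responded
        assert res.phase_summary == "normal throughout"
        assert np.isnan(res.sigma_upper)
        assert res.thermal.a_um == pytest.approx(52.9, rel=1e-9)

    def test_noiseless_recovery_reference_tiller(self, noiseless_result):
        """Noiseless simulation at the reference truth: a to machine
        precision, breakpoints within the documented procedure bias."""
        res = noiseless_result
        assert res.thermal.a_um == pytest.approx(52.9, rel=1e-9)
        assert res.sigma_upper == pytest.approx(2.70, abs=0.1)
        assert res.sigma_lower == pytest.approx(3.83, abs=0.1)
        assert res.responded and res.slow.c < 0

    def test_result_identities_hold(self, noiseless_result):
        res = noiseless_result
        assert res.sigma_lower - res.sigma_upper == pytest.approx(
            -1.0 / res.slow.c, abs=1e-10
        )
        assert res.sigma_upper == pytest.approx((1 - res.slow.i) / res.slow.c, abs=1e-10)

    def test_scale_covariance(self, noiseless_cfg):
        """Scaling all LER by k scales a by k and leaves the breakpoints
        unchanged (RGRa is scale-free)."""
        c1 = noiseless_cfg
        c2 = SimConfig(**{**c1.to_dict(), "a_true": c1.a_true * 3.0})
        r1 = fit_simulated(c1)[0]
        r2 = fit_simulated(c2)[0]
        assert r2.thermal.a == pytest.approx(3.0 * r1.thermal.a, rel=1e-9)
        assert r2.sigma_upper == pytest.approx(r1.sigma_upper, abs=1e-9)
        assert r2.sigma_lower == pytest.approx(r1.sigma_lower, abs=1e-9)

    @pytest.mark.parametrize("sigma_upper", [2.0, 2.6, 3.2])
    @pytest.mark.parametrize("gap", [1.0, 1.5])
    def test_noiseless_recovery_grid(self, sigma_upper, gap):
        """Across the physiological truth range (slow-to-arrest span >= 1
        log10 hPa, as observed in real genotypes), noiseless recovery is
        within 0.1 log10 hPa."""
        cfg = SimConfig(sigma_upper_true=sigma_upper, sigma_lower_true=sigma_upper + gap,
                        noise_sd_ler=0.0, n_replicates=1)
        res = fit_simulated(cfg)[0]
        assert abs(res.sigma_upper - sigma_upper) <= 0.1
        assert abs(res.sigma_lower - sigma_upper - gap) <= 0.1

    def test_steep_response_recovery_without_retention_on_exact_psi(self):
        """Attribution of the steep-response bias: feeding the fitter the
        exact psi curve and disabling the retained normal bin recovers a
        steep truth (span 0.5 log10 hPa) essentially exactly — so the
        residual bias in the full pipeline comes from the retention rule
        plus imputation, not from the regression stages."""
        from triphase.simdata import psi_log10_curve, simulate_experiment
        from triphase.timeseries_io import align_hourly, compute_hourly_ler, summarize_temperature

        cfg = SimConfig(sigma_upper_true=2.0, sigma_lower_true=2.5,
                        noise_sd_ler=0.0, n_replicates=1)
        growths, temp, soil = simulate_experiment(cfg)
        hours = np.arange(int(cfg.duration))
        psi = pd.DataFrame({"hour": hours,
                            "psi_log10": psi_log10_curve(hours + 0.5, cfg)})
        s = align_hourly(compute_hourly_ler(growths[0]),
                         summarize_temperature(temp), psi,
                         rewater_time=cfg.rewater_time)
        res = fit_triphase(s, FitConfig(retain_last_normal_bin=False))
        assert res.sigma_upper == pytest.approx(2.0, abs=0.02)
        assert res.sigma_lower == pytest.approx(2.5, abs=0.02)

    def test_rewatering_hours_do_not_change_fit(self, noiseless_cfg, noiseless_result):
        """Dropping the post-watering tail entirely gives the same fit as
        flag-based exclusion (up to the two extra plateau soil readings
        that then enter the imputation window)."""
        cfg = SimConfig(**{**noiseless_cfg.to_dict(), "duration": 130.0,
                           "rewater_time": None})
        res = fit_simulated(cfg)[0]
        assert res.sigma_upper == pytest.approx(noiseless_result.sigma_upper, abs=0.02)
        assert res.sigma_lower == pytest.approx(noiseless_result.sigma_lower, abs=0.02)

    def test_serialization_round_trip(self, noiseless_result, tmp_path):
        import json

        from triphase.triphase_core import results_to_csv

        d = json.loads(noiseless_result.to_json())
        assert d["tiller_id"] == noiseless_result.tiller_id
        assert d["thermal"]["a"] == pytest.approx(noiseless_result.thermal.a)
        df = results_to_csv([noiseless_result], tmp_path / "r.csv")
        assert list(df["a_um"]) == [pytest.approx(52.9, rel=1e-9)]


@settings(deadline=None, max_examples=25)
@given(
    n=st.integers(4, 10),
    seed=st.integers(0, 2**16),
)
def test_ols_matches_brute_force_minimizer(n, seed):
    """Both regressions agree with direct numerical minimisation of their
    squared-error objectives on small random instances."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(10, 30, n)
    y = 0.05 * t + rng.normal(0, 0.1, n)
    s = make_series(range(n), y, t, 1.8)
    a_fit = fit_thermal_rate(s, window_h=n).a
    best = minimize(
        lambda p: np.sum((y - p[0] * t) ** 2),
        [0.0],
        jac=lambda p: np.array([-2.0 * np.sum(t * (y - p[0] * t))]),
        method="BFGS",
        options={"gtol": 1e-14},
    )
    assert a_fit == pytest.approx(best.x[0], abs=1e-8)

    x = rng.uniform(2.0, 3.5, n)
    r = 3.2 - 1.0 * x + rng.normal(0, 0.05, n)
    pts = make_series(range(n), 0, 20.0, x, rgra=r)
    try:
        fit = fit_slow_phase(pts)
    except (NonDecreasingResponseError, InsufficientSpreadError):
        return

    def obj(p):
        resid = r - p[0] - p[1] * x
        return np.sum(resid**2)

    def grad(p):
        resid = r - p[0] - p[1] * x
        return np.array([-2.0 * resid.sum(), -2.0 * np.sum(x * resid)])

    best = minimize(obj, [0.0, -1.0], jac=grad, method="BFGS", options={"gtol": 1e-14})
    # polish: the objective is quadratic, so a Newton step from the analytic
    # Hessian lands on the minimiser to machine precision
    hess = 2.0 * np.array([[n, x.sum()], [x.sum(), np.sum(x * x)]])
    polished = best.x - np.linalg.solve(hess, grad(best.x))
    assert fit.i == pytest.approx(polished[0], abs=1e-8)
    assert fit.c == pytest.approx(polished[1], abs=1e-8)
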