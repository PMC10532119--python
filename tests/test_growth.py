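"""Logistic fitting, closed-form AUC, latency and maxOD extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from codyn.errors import AnalysisError
from codyn.growth import (FitConfig, LogisticGrowthModel, extract_growth_parameters,
                          latency, logistic_auc, logistic_od, max_od)
from codyn.io_plate import GrowthCurve

TIMES = np.arange(0.0, 24.01, 0.5)


def exact_curve(K, r, N0, times=TIMES, cid="c"):
    return GrowthCurve(cid, times, logistic_od(times, K, r, N0))


class TestFit:
    def test_exact_recovery(self):
        res = LogisticGrowthModel.from_curve(exact_curve(2.0, 0.4, 0.01)).fit()
        assert res.converged
        assert abs(res.K - 2.0) / 2.0 < 1e-6
        assert abs(res.r - 0.4) / 0.4 < 1e-6
        assert abs(res.N0 - 0.01) / 0.01 < 1e-6

    def test_flat_curve_flagged_non_growing(self):
        flat = GrowthCurve("flat", TIMES, np.full_like(TIMES, 0.05))
        res = LogisticGrowthModel.from_curve(flat).fit()
        assert not res.converged
        assert np.isnan(res.auc())

    def test_summary_smoke(self):
        res = LogisticGrowthModel.from_curve(exact_curve(2.0, 0.4, 0.01)).fit()
        text = res.summary()
        assert "K (OD)" in text and "converged" in text


class TestAuc:
    def test_constant_culture_integrates_to_window(self):
        # N0 = K: the curve sits at K, so AUC over 24 h is exactly 24*K
        assert logistic_auc(1.0, 0.5, 1.0, 24.0) == pytest.approx(24.0, rel=1e-12)

    def test_matches_adaptive_quadrature(self):
        K, r, N0 = 2.0, 0.4, 0.1
        val = logistic_auc(K, r, N0, 24.0)
        oracle, _ = quad(lambda t: logistic_od(t, K, r, N0), 0.0, 24.0, epsrel=1e-12)
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_scale_invariance_in_K(self):
        # doubling K at fixed r and N0/K ratio doubles the integral
        a = logistic_auc(1.0, 0.4, 0.01, 24.0)
        b = logistic_auc(2.0, 0.4, 0.02, 24.0)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_rejects_bad_window(self):
        with pytest.raises(AnalysisError):
            logistic_auc(2.0, 0.4, 0.01, 0.0)

    def test_closed_form_vs_dense_trapezoid_on_fits(self):
        # the fitted curve's trapezoid at dt=0.01 agrees to <1e-3 relative
        rng = np.random.default_rng(3)
        dense = np.arange(0.0, 24.0001, 0.01)
        for _ in range(10):
            K, r, N0 = rng.uniform(1, 2.5), rng.uniform(0.2, 0.5), rng.uniform(0.005, 0.02)
            od = np.clip(logistic_od(TIMES, K, r, N0) + rng.normal(0, 0.02, TIMES.shape), 0, None)
            res = LogisticGrowthModel(TIMES, od).fit()
            assert res.converged
            trap = np.trapezoid(res.predict(dense), dense)
            assert abs(res.auc() - trap) / trap < 1e-3


class TestLatency:
    def test_already_above_threshold(self):
        c = GrowthCurve("c", TIMES, np.linspace(0.3, 2.0, len(TIMES)))
        assert latency(c, 0.25) == 0.0

    def test_never_crossing_is_undefined(self):
        c = GrowthCurve("c", TIMES, np.full_like(TIMES, 0.1))
        assert np.isnan(latency(c, 0.25))

    def test_matches_closed_form_root(self):
        K, r, N0 = 2.0, 0.43, 0.01
        root = brentq(lambda t: logistic_od(t, K, r, N0) - 0.25, 0.0, 24.0)
        dense = exact_curve(K, r, N0, np.arange(0.0, 24.001, 0.01))
        assert latency(dense, 0.25) == pytest.approx(root, abs=1e-4)
        coarse = exact_curve(K, r, N0)
        assert latency(coarse, 0.25) == pytest.approx(root, abs=0.05)

    def test_step_mode_returns_sample_time(self):
        c = exact_curve(2.0, 0.43, 0.01)
        t_step = latency(c, 0.25, interpolate=False)
        assert t_step in c.times
        assert t_step >= latency(c, 0.25, interpolate=True)

    @given(st.lists(st.floats(0.0, 3.0), min_size=4, max_size=30),
           st.floats(0.05, 1.0), st.floats(0.0, 1.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, od, thr, extra):
        c = GrowthCurve("c", np.arange(len(od), dtype=float) * 0.5, od)
        lo, hi = latency(c, thr), latency(c, thr + extra)
        if not np.isnan(lo) and not np.isnan(hi):
            assert hi >= lo
        elif np.isnan(lo):
            assert np.isnan(hi)


class TestMaxOd:
    def test_monotone_curve_gives_last_value(self):
        c = GrowthCurve("c", TIMES, np.linspace(0.0, 2.0, len(TIMES)))
        assert max_od(c) == 2.0

    def test_overshoot_gives_peak_not_final(self):
        od = np.concatenate([np.linspace(0, 2.0, 30), np.linspace(2.0, 1.5, 19)])
        c = GrowthCurve("c", TIMES, od)
        assert max_od(c) == 2.0

    def test_noisy_plateau_within_noise_of_K(self):
        rng = np.random.default_rng(11)
        K, sigma = 2.0, 0.02
        od = np.clip(logistic_od(TIMES, K, 0.4, 0.01) + rng.normal(0, sigma, TIMES.shape), 0, None)
        assert abs(max_od(GrowthCurve("c", TIMES, od)) - K) < 3 * sigma + 3 * sigma  # peak of noise


class TestExtract:
    def test_exact_logistic_bundles_all_closed_forms(self):
        K, r, N0 = 2.0, 0.4, 0.01
        gp = extract_growth_parameters(exact_curve(K, r, N0), FitConfig())
        assert gp.converged
        assert gp.r == pytest.approx(r, rel=1e-6)
        assert gp.max_od == pytest.approx(logistic_od(24.0, K, r, N0), rel=1e-9)
        assert gp.auc == pytest.approx(logistic_auc(K, r, N0, 24.0), rel=1e-6)
        root = brentq(lambda t: logistic_od(t, K, r, N0) - 0.25, 0, 24)
        assert gp.latency_h == pytest.approx(root, abs=0.05)

    def test_non_growing_curve_keeps_direct_measures(self):
        flat = GrowthCurve("flat", TIMES, np.full_like(TIMES, 0.05))
        gp = extract_growth_parameters(flat)
        assert not gp.converged
        assert np.isnan(gp.latency_h) and np.isnan(gp.r) and np.isnan(gp.auc)
        assert gp.max_od == pytest.approx(0.05)

    def test_window_truncation(self):
        times = np.arange(0.0, 30.01, 0.5)
        od = logistic_od(times, 2.0, 0.4, 0.01)
        od[times > 24] = 5.0  # corrupt data beyond the window must not matter
        gp = extract_growth_parameters(GrowthCurve("c", times, od))
        assert gp.max_od == pytest.approx(logistic_od(24.0, 2.0, 0.4, 0.01), rel=1e-6)
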