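"""Variance traces, scaling-law fits, and maxima marking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizuredyn import early_warning as ew
from seizuredyn import sde


class TestSlidingVariance:
    def test_constant_series_gives_zero(self):
        tr = ew.sliding_variance(np.full(10_000, 3.7), 5000, 50)
        assert np.all(tr.values == 0.0)

    def test_iid_normal_matches_sampling_distribution(self, rng):
        x = rng.standard_normal(20_000)
        tr = ew.sliding_variance(x, 5000, 500)
        se = np.sqrt(2.0 / 4999)
        assert np.all(np.abs(tr.values - 1.0) < 3 * se)

    def test_alternating_series_closed_form(self):
        w = 100
        x = np.tile([1.0, -1.0], 500)
        tr = ew.sliding_variance(x, w, 10)
        np.testing.assert_allclose(tr.values, w / (w - 1))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ew.sliding_variance(np.zeros(10), 100, 5)

    @given(st.integers(2, 30), st.integers(1, 7), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_direct_window_variance(self, window, step, seed):
        x = np.random.default_rng(seed).normal(size=80)
        tr = ew.sliding_variance(x, window, step)
        for start, v in zip(range(0, 80 - window + 1, step), tr.values):
            assert v == pytest.approx(np.var(x[start : start + window], ddof=1),
                                      abs=1e-10)


class TestEnsembleVariance:
    def test_copies_equal_single_path_variance(self):
        x = np.sin(np.linspace(0, 20, 4000))
        path = sde.SamplePath(times=np.arange(4000) * 1e-3,
                              states=x[np.newaxis], dt=1e-3)
        single = ew.sliding_variance(x, 500, 100)
        ens = ew.ensemble_variance([path] * 100, 0, 500, 100)
        np.testing.assert_allclose(ens.values, single.values, rtol=1e-12)

    def test_ou_ensemble_approaches_stationary_level(self):
        paths = []
        base = np.random.default_rng(9)
        for k in range(50):
            paths.append(sde.euler_maruyama(lambda s: -s, [0.5], [0.0], 1e-2,
                                            20_000, seed=int(base.integers(2**31))))
        # window of 50 OU relaxation times: short-window bias ~ 2 tau / T = 4%
        tr = ew.ensemble_variance(paths, 0, 5000, 5000)
        assert abs(tr.values[-1] - 0.125) / 0.125 < 0.10

    def test_empty_or_heterogeneous_collections_rejected(self):
        with pytest.raises(ValueError):
            ew.ensemble_variance([], 0, 10, 5)
        a = sde.SamplePath(np.arange(100) * 0.1, np.zeros((1, 100)), 0.1)
        b = sde.SamplePath(np.arange(50) * 0.1, np.zeros((1, 50)), 0.1)
        with pytest.raises(ValueError):
            ew.ensemble_variance([a, b], 0, 10, 5)


class TestFoldVarianceFit:
    def test_noiseless_self_fit_recovers_constant_exactly(self):
        x = np.linspace(-2.0, -1.1, 50)
        d_true = 0.01
        trace = ew.VarianceTrace(np.arange(50), d_true / (2 * (x**2 - 1)), 10, 1)
        fit = ew.fit_fold_variance(trace, x)
        assert fit.coefficients["D"] == pytest.approx(d_true, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_pole_divergence_toward_fold(self):
        d = 1.0
        var_at = lambda x: d / (2 * (x**2 - 1))  # noqa: E731
        assert var_at(-1.0001) > 1e3 * var_at(-2.0)

    def test_positions_off_branch_rejected(self):
        trace = ew.VarianceTrace(np.arange(3), np.ones(3), 10, 1)
        with pytest.raises(ValueError, match="attracting branch"):
            ew.fit_fold_variance(trace, np.array([-1.5, -0.9, -1.2]))


class TestInverseVarianceFit:
    def test_exact_linear_recovery(self):
        t = np.arange(50, dtype=float)
        inv = 10.0 - 0.1 * t
        trace = ew.VarianceTrace(t, 1.0 / inv, 10, 1)
        fit = ew.fit_inverse_variance_linear(trace)
        assert fit.coefficients["slope"] == pytest.approx(-0.1, rel=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(10.0, rel=1e-9)
        assert fit.predicted_transition == pytest.approx(100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_trace_gives_no_prediction(self):
        trace = ew.VarianceTrace(np.arange(20), np.full(20, 2.0), 10, 1)
        fit = ew.fit_inverse_variance_linear(trace)
        assert fit.predicted_transition is None
        assert fit.coefficients["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        trace = ew.VarianceTrace(np.arange(3), np.array([1.0, 0.0, 1.0]), 10, 1)
        with pytest.raises(ValueError, match="zero variance"):
            ew.fit_inverse_variance_linear(trace)


class TestMarkedMaxima:
    def test_single_triangular_peak_marked(self):
        v = np.zeros(200)
        v[95:106] = np.concatenate([np.arange(6), np.arange(5)[::-1]])
        res = ew.find_marked_maxima(v, n_intervals=20)
        assert list(res.marked_indices) == [100]

    def test_monotone_series_has_no_marks(self):
        res = ew.find_marked_maxima(np.arange(200.0), n_intervals=20)
        assert res.marked_indices.size == 0

    def test_sinusoid_peaks_counted_exactly(self):
        # 5 interior peaks across the series
        t = np.linspace(0, 2 * np.pi * 5, 400, endpoint=False)
        v = np.sin(t - np.pi / 2)
        res = ew.find_marked_maxima(v, n_intervals=20)
        peaks = np.where((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
        assert res.marked_indices.size == 5
        assert set(res.marked_indices) <= set(peaks)

    @given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_positive_affine_rescaling(self, scale, shift, seed):
        v = np.random.default_rng(seed).normal(size=200)
        a = ew.find_marked_maxima(v, 10)
        b = ew.find_marked_maxima(scale * v + shift, 10)
        assert np.array_equal(a.marked_indices, b.marked_indices)


class TestTrendModels:
    def test_exact_line_wins_with_zero_residual(self):
        t = np.arange(30.0)
        cmp_ = ew.compare_trend_models(t, 2.0 + 0.5 * t)
        assert cmp_["winner"] == "linear"
        assert cmp_["rss"]["linear"] == pytest.approx(0.0, abs=1e-16)

    def test_exponential_data_prefers_exponential(self):
        t = np.arange(40.0)
        cmp_ = ew.compare_trend_models(t, 3.0 * np.exp(0.1 * t))
        assert cmp_["winner"] == "exponential"

    def test_power_data_prefers_power(self):
        t = np.arange(40.0)
        cmp_ = ew.compare_trend_models(t, 2.0 * (t + 1.0) ** 0.6)
        assert cmp_["winner"] == "power"
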