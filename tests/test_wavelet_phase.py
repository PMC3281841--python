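"""Hilbert wavelet bands, phase vectors, locking intervals and synchrony."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizuredyn import wavelet_phase as wp

FS = 256.0


def tone(freq, n, fs=FS, phase=0.0):
    return np.cos(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestScaleBand:
    @pytest.mark.parametrize(
        "fs, j, expected",
        [(256, 3, (16, 32)), (256, 4, (8, 16)), (256, 5, (4, 8)), (1, 1, (0.25, 0.5))],
    )
    def test_dyadic_bands(self, fs, j, expected):
        assert wp.scale_band(fs, j) == pytest.approx(expected)

    def test_printed_band_sets_at_inferred_rates(self):
        # 256 Hz: 16-32 / 8-16 / 4-8; 200 Hz: 12-25 / 6-12 / 3-6 after
        # truncation to the printed integer band edges
        assert [wp.scale_band(256, j) for j in (3, 4, 5)] == [
            (16, 32), (8, 16), (4, 8)]
        printed = [(12, 25), (6, 12), (3, 6)]
        got = [tuple(int(e) for e in wp.scale_band(200, j)) for j in (3, 4, 5)]
        assert got == printed


class TestHilbertWaveletTransform:
    @pytest.mark.parametrize("engine", ["filter_bank", "fft_oracle"])
    def test_band_center_tone_phase_slope(self, engine):
        f = np.sqrt(16 * 32)
        n = 2**14
        w = wp.hilbert_wavelet_transform(tone(f, n), FS, [3], engine=engine)[0]
        interior = slice(1000, -1000)
        phase = np.unwrap(np.angle(w.coefficients[interior]))
        slope = np.polyfit(np.arange(n)[interior] / FS, phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_disjoint_tones_stay_in_their_bands(self):
        n = 2**15
        x = tone(22.6, n) + tone(5.6, n)
        bands = wp.hilbert_wavelet_transform(x, FS, [3, 5], engine="fft_oracle")
        for w in bands:
            energy = np.mean(np.abs(w.coefficients) ** 2)
            # each band holds its own unit-amplitude tone: |W|^2 ~ 1
            assert energy == pytest.approx(1.0, rel=0.05)

    def test_engines_agree_in_phase_away_from_boundaries(self, rng):
        n = 2**14
        x = tone(22.6, n) + 0.3 * rng.standard_normal(n)
        wf = wp.hilbert_wavelet_transform(x, FS, [3])[0].coefficients
        wo = wp.hilbert_wavelet_transform(x, FS, [3], engine="fft_oracle")[0].coefficients
        interior = slice(2000, -2000)
        dphi = np.angle(wf[interior] * np.conj(wo[interior]))
        assert np.percentile(np.abs(dphi), 95) < 0.1

    def test_white_noise_adjacent_scale_energy_halving(self, rng):
        x = rng.standard_normal(2**16)
        bands = wp.hilbert_wavelet_transform(x, FS, [3, 4, 5], engine="fft_oracle")
        e = [np.mean(np.abs(w.coefficients) ** 2) for w in bands]
        assert e[0] / e[1] == pytest.approx(2.0, rel=0.1)
        assert e[1] / e[2] == pytest.approx(2.0, rel=0.1)

    def test_short_series_rejected_with_minimum_length(self):
        with pytest.raises(ValueError, match="at least"):
            wp.hilbert_wavelet_transform(np.zeros(100), FS, [6])


class TestComplexPhaseVector:
    def _coeffs(self, values):
        return wp.AnalyticScaleCoefficients(3, np.asarray(values, complex), FS)

    def test_self_comparison_is_unity(self, rng):
        w = self._coeffs(rng.standard_normal(100) + 1j * rng.standard_normal(100))
        c = wp.complex_phase_vector(w, w)
        np.testing.assert_allclose(c.values[c.defined], 1.0, atol=1e-12)

    def test_constant_rotation_recovered(self, rng):
        a = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        theta = 0.7
        c = wp.complex_phase_vector(self._coeffs(a), self._coeffs(a * np.exp(-1j * theta)))
        np.testing.assert_allclose(np.angle(c.values[c.defined]), theta, atol=1e-12)

    def test_independent_phases_average_out(self, rng):
        n = 10_000
        a = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        b = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        c = wp.complex_phase_vector(self._coeffs(a), self._coeffs(b))
        assert np.abs(np.mean(c.values)) <= 3 / np.sqrt(n)

    def test_scale_mismatch_rejected(self):
        a = wp.AnalyticScaleCoefficients(3, np.ones(10, complex), FS)
        b = wp.AnalyticScaleCoefficients(4, np.ones(10, complex), FS)
        with pytest.raises(ValueError, match="scale"):
            wp.complex_phase_vector(a, b)


class TestSmoothedPhaseDifference:
    def _cpv(self, values, defined=None):
        values = np.asarray(values, complex)
        if defined is None:
            defined = np.ones(values.size, bool)
        return wp.ComplexPhaseVector(values, defined, 3)

    def test_constant_phase_vector(self):
        c = self._cpv(np.full(100, np.exp(1j * np.pi / 6)))
        p = wp.smoothed_phase_difference(c, 5)
        np.testing.assert_allclose(p.phase_diff, np.pi / 6, atol=1e-12)
        np.testing.assert_allclose(p.significance, 1.0, atol=1e-12)

    def test_antiphase_cancellation(self):
        vals = np.where(np.arange(100) % 2 == 0, np.exp(1j * np.pi / 2),
                        np.exp(-1j * np.pi / 2))
        p = wp.smoothed_phase_difference(self._cpv(vals), 5)
        assert np.all(p.significance[2:-2] < 0.05)

    def test_drifting_phase_dirichlet_significance(self):
        omega, L, n = 0.1, 21, 500
        c = self._cpv(np.exp(1j * omega * np.arange(n)))
        p = wp.smoothed_phase_difference(c, L)
        expected = np.abs(np.sin(omega * L / 2) / (L * np.sin(omega / 2))) ** 2
        interior = slice(L, n - L)
        np.testing.assert_allclose(p.significance[interior], expected, rtol=1e-9)
        # phase tracks the window-center value
        np.testing.assert_allclose(p.phase_diff[interior],
                                   np.angle(np.exp(1j * omega * np.arange(n)))[interior],
                                   atol=1e-9)

    def test_undefined_windows_flagged(self):
        c = self._cpv(np.ones(20), defined=np.zeros(20, bool))
        p = wp.smoothed_phase_difference(c, 5)
        assert np.all(p.significance == 0.0)
        assert np.all(np.isnan(p.phase_diff))

    def test_even_smoothing_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            wp.smoothed_phase_difference(self._cpv(np.ones(10)), 4)


class TestPhaseLockingIntervals:
    def _series(self, phase, sig):
        phase = np.asarray(phase, float)
        return wp.PhaseSeries(phase, np.asarray(sig, float), 1,
                              np.isfinite(phase))

    def test_fully_locked_single_interval(self):
        p = self._series(np.zeros(50), np.ones(50))
        res = wp.phase_locking_intervals(p, np.pi / 4, 0.5)
        assert res.intervals == [(0, 50)]

    def test_significance_gate_blocks_everything(self):
        p = self._series(np.zeros(50), np.full(50, 0.4))
        assert wp.phase_locking_intervals(p).intervals == []

    def test_square_wave_phase_yields_exact_runs(self):
        phase = np.concatenate([np.zeros(100), np.full(100, np.pi)] * 3)
        p = self._series(phase, np.ones(600))
        res = wp.phase_locking_intervals(p, np.pi / 4, 0.5)
        assert res.intervals == [(0, 100), (200, 300), (400, 500)]

    @given(st.floats(0.1, np.pi), st.floats(0.1, np.pi))
    @settings(max_examples=25, deadline=None)
    def test_raising_phase_threshold_never_shrinks_intervals(self, th1, th2):
        rng = np.random.default_rng(0)
        p = self._series(rng.uniform(-np.pi, np.pi, 300), np.ones(300))
        lo, hi = sorted([th1, th2])
        m_lo = wp.phase_locking_intervals(p, lo).mask(300)
        m_hi = wp.phase_locking_intervals(p, hi).mask(300)
        assert np.all(m_hi[m_lo])  # every lo-locked sample stays locked at hi


class TestSynchronyMeasures:
    def test_identical_channels_fully_locked(self, rng):
        x = rng.standard_normal(12_000)
        signals = np.tile(x, (4, 1))
        tr = wp.plw_measure(signals, FS, 3, window_len=2000, step=1000)
        np.testing.assert_allclose(tr.values, 1.0, atol=1e-12)

    def test_half_locked_pairs_give_half(self):
        # 2 identical + 2 identical but mutually independent channels:
        # 2 of 6 pairs locked, 4 independent -> PLW ~ 2/6 + small
        rng = np.random.default_rng(5)
        a = rng.standard_normal(12_000)
        b = rng.standard_normal(12_000)
        signals = np.stack([a, a, b, b])
        tr = wp.plw_measure(signals, FS, 3, window_len=2000, step=1000)
        locked_floor = 2 / 6
        assert np.all(tr.values >= locked_floor - 1e-9)
        assert tr.values.mean() < locked_floor + 0.15

    def test_independent_channels_stay_near_zero(self):
        rng = np.random.default_rng(11)
        signals = rng.standard_normal((6, 30_000))
        tr = wp.plw_measure(signals, FS, 3, window_len=5000, step=2500)
        assert np.all(tr.values <= 0.1)

    def test_plw_invariant_under_channel_relabeling(self, rng):
        signals = rng.standard_normal((4, 8192))
        tr1 = wp.plw_measure(signals, FS, 3, window_len=2048, step=1024)
        tr2 = wp.plw_measure(signals[::-1], FS, 3, window_len=2048, step=1024)
        np.testing.assert_allclose(tr1.values, tr2.values, atol=1e-12)

    def test_null_plw_decreases_with_window_length(self):
        rng = np.random.default_rng(3)
        signals = rng.standard_normal((4, 40_000))
        short = wp.plw_measure(signals, FS, 4, window_len=1000, step=5000)
        long = wp.plw_measure(signals, FS, 4, window_len=20_000, step=5000)
        assert long.values.mean() <= short.values.mean()

    def test_fewer_than_two_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="2 channels"):
            wp.plw_measure(rng.standard_normal((1, 4096)), FS, 3,
                           window_len=1024, step=512)


class TestMeanPhaseCoherence:
    def test_constant_phase_gives_one(self):
        assert wp.mean_phase_coherence(np.full(100, 1.2)) == pytest.approx(1.0)

    def test_symmetric_four_point_set_gives_zero(self):
        phases = np.repeat([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], 25)
        assert wp.mean_phase_coherence(phases) == pytest.approx(0.0, abs=1e-12)

    def test_wrapped_normal_matches_closed_form(self, rng):
        s = 0.8
        n = 100_000
        phases = rng.normal(0.0, s, n)
        r = wp.mean_phase_coherence(phases)
        expected = np.exp(-(s**2) / 2)
        se = np.sqrt((1 - expected**2) / n)  # conservative resultant-length SE
        assert abs(r - expected) < 3 * max(se, 1e-3)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wp.mean_phase_coherence(np.array([np.nan]))


class TestScaleOnsets:
    def _ramp_traces(self, onsets, n=400, noise=0.005, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.arange(n) * 250.0
        traces = []
        for j, onset in zip((3, 4, 5), onsets):
            base = 0.2 + noise * rng.standard_normal(n)
            ramp = 0.4 * np.maximum(0.0, centers - onset) / (centers[-1] - onset)
            traces.append(wp.SynchronyTrace(centers, base + ramp, "plw", j))
        return centers, traces

    def test_known_ramps_recovered_in_order(self):
        onsets = [40_000.0, 55_000.0, 70_000.0]
        centers, traces = self._ramp_traces(onsets)
        res = wp.detect_scale_onsets(traces, centers[-1], (0.0, 30_000.0))
        got = [r.onset_time for r in res]
        assert all(o is not None for o in got)
        assert got == sorted(got)
        for o_true, o_got in zip(onsets, got):
            assert abs(o_got - o_true) < 10_000  # window+smoothing slack

    def test_constant_trace_has_no_onset(self):
        centers = np.arange(200) * 250.0
        tr = wp.SynchronyTrace(centers, np.full(200, 0.3), "plw", 3)
        res = wp.detect_scale_onsets([tr], centers[-1], (0.0, 20_000.0))
        assert res[0].onset_time is None

    def test_exact_linear_ramp_wins_fit_comparison(self):
        centers, traces = self._ramp_traces([40_000.0], noise=0.0)
        res = wp.detect_scale_onsets(traces[:1], centers[-1], (0.0, 30_000.0))
        assert res[0].fit_comparison["winner"] == "linear"
        assert res[0].fit_comparison["rss"]["linear"] == pytest.approx(0.0, abs=1e-12)
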