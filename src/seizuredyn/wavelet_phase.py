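"""Hilbert wavelet decomposition and phase-locking synchrony measures.

A real multichannel signal is decomposed into dyadic frequency bands
(fs/2^(j+1), fs/2^j] by an undecimated (maximal-overlap) dyadic filter
bank whose two branches form an exact Hilbert pair, yielding an
approximately analytic band signal per scale j aligned to the input time
grid.  Two engines are provided:

* ``"filter_bank"`` (default): the squared-magnitude response of a
  Daubechies least-asymmetric wavelet cascade, applied zero-phase; the
  imaginary branch is the exact discrete Hilbert transform of the real
  branch, so the output spectrum is one-sided by construction.
* ``"fft_oracle"``: an ideal analytic dyadic band-pass (brick-wall in the
  frequency domain), used as an independent reference in tests.

From the per-scale analytic signals the module derives, for a channel
pair, the instantaneous complex phase vector C(t), its moving average
(a less noisy phase estimate with significance |mean C|^2), intervals of
phase locking (PLI), the normalized pair-time fraction of locking (PLW,
in [0, 1]) over sliding windows, and the mean phase coherence
R = |<exp(i dphi)>|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .early_warning import compare_trend_models

__all__ = [
    "AnalyticScaleCoefficients",
    "ComplexPhaseVector",
    "PhaseSeries",
    "PliSet",
    "SynchronyTrace",
    "OnsetResult",
    "scale_band",
    "hilbert_wavelet_transform",
    "complex_phase_vector",
    "smoothed_phase_difference",
    "phase_locking_intervals",
    "plw_measure",
    "windowed_mpc",
    "mean_phase_coherence",
    "detect_scale_onsets",
    "default_smoothing_len",
]

DEFAULT_PHASE_THRESHOLD = np.pi / 4
DEFAULT_SIGNIFICANCE_THRESHOLD = 0.5
_MODULUS_FLOOR_REL = 1e-10  # relative to the rms coefficient modulus


def scale_band(fs: float, j: int) -> tuple[float, float]:
    """Frequency band (f_lo, f_hi) of dyadic wavelet scale j at rate fs."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if j < 1:
        raise ValueError("scale index must be >= 1")
    return (fs / 2 ** (j + 1), fs / 2**j)


def default_smoothing_len(j: int) -> int:
    """Scale-dependent smoothing span: 2^(j+2) samples, odd-adjusted.

    About three cycles of the band-center frequency at every scale — long
    enough that the significance of independent signals (whose band
    correlation time is ~2^(j+1) samples) falls below the 0.5 gate, short
    enough to track locking episodes.
    """
    n = 2 ** (j + 2)
    return n + 1 if n % 2 == 0 else n


@dataclass
class AnalyticScaleCoefficients:
    """Approximately analytic band signal at one dyadic scale."""

    scale_j: int
    coefficients: np.ndarray
    fs: float

    @property
    def band_hz(self) -> tuple[float, float]:
        return scale_band(self.fs, self.scale_j)

    def __len__(self) -> int:
        return self.coefficients.size


@dataclass
class ComplexPhaseVector:
    """Unit-modulus relative phase between two band signals.

    ``defined`` flags samples where both input moduli exceed the floor;
    undefined samples carry value 0 and never contribute to averages.
    """

    values: np.ndarray
    defined: np.ndarray
    scale_j: int


@dataclass
class PhaseSeries:
    """Smoothed phase difference with a per-sample significance estimate.

    phase_diff in (-pi, pi]; significance = |moving average of C|^2 in
    [0, 1]; samples with no defined neighbours are flagged undefined with
    significance 0.
    """

    phase_diff: np.ndarray
    significance: np.ndarray
    smoothing_len: int
    defined: np.ndarray


@dataclass
class PliSet:
    """Sorted, disjoint half-open sample-index intervals of phase locking."""

    intervals: list[tuple[int, int]]
    phase_threshold: float
    significance_threshold: float

    def total_samples(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def mask(self, n: int) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for a, b in self.intervals:
            m[a:b] = True
        return m


@dataclass
class SynchronyTrace:
    """Windowed synchrony values (PLW, MPC, or MLCC) on a common grid."""

    window_centers: np.ndarray
    values: np.ndarray
    measure: str
    scale_j: int | None = None

    def __len__(self) -> int:
        return self.values.size


def _cascade_response(n: int, j: int, wavelet: str) -> np.ndarray:
    """|H_j|^ of the undecimated wavelet cascade on an n-point DFT grid.

    Standard a-trous construction: the level-j wavelet response is the
    high-pass response dilated j-1 times composed with the first j-1
    low-pass stages.  Only the magnitude is used (zero-phase filtering),
    normalized to unit peak gain.
    """
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo, dtype=float)
    h = np.asarray(w.dec_hi, dtype=float)
    gf = np.fft.fft(g, n)
    hf = np.fft.fft(h, n)
    idx = np.arange(n)
    resp = hf[(2 ** (j - 1) * idx) % n].copy()
    for level in range(j - 1):
        resp *= gf[(2**level * idx) % n]
    mag = np.abs(resp)
    peak = mag.max()
    if peak == 0:
        raise ValueError(f"degenerate cascade response at scale {j}")
    return mag / peak


def _analytic_mask(n: int) -> np.ndarray:
    """Doubling mask turning a real-signal DFT into an analytic-signal DFT."""
    m = np.zeros(n)
    m[0] = 1.0
    if n % 2 == 0:
        m[n // 2] = 1.0
        m[1 : n // 2] = 2.0
    else:
        m[1 : (n + 1) // 2] = 2.0
    return m


def hilbert_wavelet_transform(
    series,
    fs: float,
    scales: Sequence[int],
    engine: str = "filter_bank",
    wavelet: str = "sym8",
) -> list[AnalyticScaleCoefficients]:
    """Analytic dyadic band signals of a real series at the given scales.

    The input is reflection-padded on both sides before circular filtering
    to suppress wrap-around at the boundaries.  Both engines return
    coefficients aligned to the input grid (zero phase delay).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if fs <= 0:
        raise ValueError("fs must be positive")
    jmax = max(scales)
    min_len = 2 ** (jmax + 2)
    if x.size < min_len:
        raise ValueError(
            f"series too short for scale {jmax}: need at least {min_len} samples"
        )
    if engine not in ("filter_bank", "fft_oracle"):
        raise ValueError(f"unknown engine {engine!r}")

    n = x.size
    pad = min(n, 4 * 2**jmax * 16)
    xp = np.concatenate([x[pad - 1 :: -1] if pad else x[:0], x, x[: -pad - 1 : -1]])
    m = xp.size
    X = np.fft.fft(xp)
    freqs = np.fft.fftfreq(m, d=1.0 / fs)
    analytic = _analytic_mask(m)

    out = []
    for j in scales:
        if engine == "fft_oracle":
            f_lo, f_hi = scale_band(fs, j)
            resp = ((np.abs(freqs) > f_lo) & (np.abs(freqs) <= f_hi)).astype(float)
        else:
            resp = _cascade_response(m, j, wavelet)
        coeff = np.fft.ifft(X * resp * analytic)[pad : pad + n]
        out.append(AnalyticScaleCoefficients(scale_j=j, coefficients=coeff, fs=fs))
    return out


def complex_phase_vector(
    Wa: AnalyticScaleCoefficients,
    Wb: AnalyticScaleCoefficients,
    modulus_floor: float | None = None,
) -> ComplexPhaseVector:
    """Instantaneous complex phase vector C = Wa conj(Wb) / (|Wa| |Wb|).

    Samples where either modulus falls below the floor (default: 1e-10 of
    that signal's rms modulus) are flagged undefined.
    """
    if Wa.scale_j != Wb.scale_j:
        raise ValueError("scale mismatch between the two coefficient series")
    a, b = Wa.coefficients, Wb.coefficients
    if a.size != b.size:
        raise ValueError("coefficient length mismatch")
    ma, mb = np.abs(a), np.abs(b)
    if modulus_floor is None:
        floor_a = _MODULUS_FLOOR_REL * np.sqrt(np.mean(ma**2))
        floor_b = _MODULUS_FLOOR_REL * np.sqrt(np.mean(mb**2))
    else:
        floor_a = floor_b = modulus_floor
    defined = (ma > floor_a) & (mb > floor_b)
    values = np.zeros(a.size, dtype=complex)
    values[defined] = a[defined] * np.conj(b[defined]) / (ma[defined] * mb[defined])
    return ComplexPhaseVector(values=values, defined=defined, scale_j=Wa.scale_j)


def smoothed_phase_difference(C: ComplexPhaseVector, smoothing_len: int) -> PhaseSeries:
    """Centered moving average of the phase vector; arg and |.|^2 thereof.

    Undefined samples are excluded from the mean.  ``smoothing_len`` must be
    odd so the window is centered.
    """
    if smoothing_len < 1 or smoothing_len % 2 == 0:
        raise ValueError("smoothing_len must be odd and >= 1")
    vals = C.values
    kernel = np.ones(smoothing_len)
    num = np.convolve(vals, kernel, mode="same")
    cnt = np.convolve(C.defined.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, num / np.maximum(cnt, 1.0), 0.0 + 0.0j)
    defined = cnt > 0
    phase = np.angle(mean)
    phase[phase == -np.pi] = np.pi
    phase[~defined] = np.nan
    significance = np.minimum(np.abs(mean) ** 2, 1.0)
    significance[~defined] = 0.0
    return PhaseSeries(
        phase_diff=phase,
        significance=significance,
        smoothing_len=smoothing_len,
        defined=defined,
    )


def locking_mask(
    p: PhaseSeries,
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD,
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD,
) -> np.ndarray:
    """Boolean per-sample phase-locking condition."""
    if not (0 < phase_threshold <= np.pi):
        raise ValueError("phase_threshold must lie in (0, pi]")
    if not (0 < significance_threshold <= 1):
        raise ValueError("significance_threshold must lie in (0, 1]")
    with np.errstate(invalid="ignore"):
        return (
            p.defined
            & (np.abs(np.where(p.defined, p.phase_diff, np.inf)) < phase_threshold)
            & (p.significance > significance_threshold)
        )


def phase_locking_intervals(
    p: PhaseSeries,
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD,
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD,
) -> PliSet:
    """Maximal runs where |dphi| < phase_threshold and significance > gate.

    Intervals are half-open, 0-based sample-index ranges; undefined samples
    can never belong to an interval.
    """
    mask = locking_mask(p, phase_threshold, significance_threshold)
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    stops = np.where(d == -1)[0]
    return PliSet(
        intervals=list(zip(starts.tolist(), stops.tolist())),
        phase_threshold=phase_threshold,
        significance_threshold=significance_threshold,
    )


def _window_grid(n: int, window_len: int, step: int) -> np.ndarray:
    if window_len > n:
        raise ValueError(f"series too short: length {n} < window_len {window_len}")
    return np.arange(0, n - window_len + 1, step)


def _windowed_mean_of_mask(mask_sum: np.ndarray, window_len: int, step: int):
    starts = _window_grid(mask_sum.size, window_len, step)
    c = np.concatenate([[0.0], np.cumsum(mask_sum)])
    return starts, (c[starts + window_len] - c[starts])


def _pair_phase_series(
    signals: np.ndarray,
    fs: float,
    scale_j: int,
    smoothing_len: int | None,
    engine: str,
) -> list[tuple[tuple[int, int], PhaseSeries]]:
    n_ch = signals.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    L = smoothing_len if smoothing_len is not None else default_smoothing_len(scale_j)
    coeffs = [
        hilbert_wavelet_transform(signals[i], fs, [scale_j], engine=engine)[0]
        for i in range(n_ch)
    ]
    out = []
    for i, k in itertools.combinations(range(n_ch), 2):
        C = complex_phase_vector(coeffs[i], coeffs[k])
        out.append(((i, k), smoothed_phase_difference(C, L)))
    return out


def plw_measure(
    signals,
    fs: float,
    scale_j: int,
    window_len: int = 5000,
    step: int = 50,
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD,
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD,
    smoothing_len: int | None = None,
    engine: str = "filter_bank",
) -> SynchronyTrace:
    """Windowed phase-locking fraction over all unordered channel pairs.

    Per window the total number of phase-locked samples summed over the
    N(N-1)/2 pairs is divided by (N(N-1)/2) * window_len, confining the
    measure to [0, 1]; 1 means every pair locked throughout the window.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    pairs = _pair_phase_series(signals, fs, scale_j, smoothing_len, engine)
    n = signals.shape[1]
    total = np.zeros(n)
    for _, ps in pairs:
        total += locking_mask(ps, phase_threshold, significance_threshold)
    starts, sums = _windowed_mean_of_mask(total, window_len, step)
    values = sums / (len(pairs) * window_len)
    return SynchronyTrace(
        window_centers=starts + window_len // 2,
        values=values,
        measure="plw",
        scale_j=scale_j,
    )


def mean_phase_coherence(phase_diff) -> float:
    """Resultant length R = |<exp(i dphi)>| of a phase-difference series.

    1 means perfect locking, 0 a uniform phase distribution.  NaN entries
    (undefined phases) are excluded; an empty series raises.
    """
    phi = np.asarray(phase_diff, dtype=float)
    phi = phi[np.isfinite(phi)]
    if phi.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(np.exp(1j * phi))))


def windowed_mpc(
    signals,
    fs: float,
    scale_j: int,
    window_len: int = 5000,
    step: int = 50,
    smoothing_len: int | None = None,
    engine: str = "filter_bank",
) -> SynchronyTrace:
    """Mean phase coherence per sliding window, averaged over channel pairs.

    Uses the wavelet-derived smoothed phase differences; per pair and
    window R = |mean of exp(i dphi)| over defined samples, then the pair
    average.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    pairs = _pair_phase_series(signals, fs, scale_j, smoothing_len, engine)
    n = signals.shape[1]
    starts = _window_grid(n, window_len, step)
    acc = np.zeros(starts.size)
    for _, ps in pairs:
        phasor = np.where(ps.defined, np.exp(1j * np.nan_to_num(ps.phase_diff)), 0.0)
        csum = np.concatenate([[0.0 + 0.0j], np.cumsum(phasor)])
        cnt = np.concatenate([[0.0], np.cumsum(ps.defined.astype(float))])
        num = csum[starts + window_len] - csum[starts]
        den = np.maximum(cnt[starts + window_len] - cnt[starts], 1.0)
        acc += np.abs(num) / den
    values = acc / len(pairs)
    return SynchronyTrace(
        window_centers=starts + window_len // 2,
        values=values,
        measure="mpc",
        scale_j=scale_j,
    )


@dataclass
class OnsetResult:
    """Detected synchronization-rise onset for one scale."""

    scale_j: int
    onset_time: float | None
    baseline_level: float
    linear_fit: dict | None
    fit_comparison: dict | None


def detect_scale_onsets(
    traces: Sequence[SynchronyTrace],
    transition_time: float,
    baseline_range: tuple[float, float],
) -> list[OnsetResult]:
    """Per-scale onset of the sustained pre-transition synchronization rise.

    The onset is the last window (before ``transition_time``) at which the
    trace is still within baseline mean + 2 baseline SD, such that the
    trace stays above that level from there through the transition.  A
    linear model is fitted on [onset, transition] and compared against
    power-law and exponential alternatives by residual sum of squares.
    """
    t0, t1 = baseline_range
    if not t1 <= transition_time:
        raise ValueError("baseline_range must precede transition_time")
    results = []
    for tr in traces:
        centers = np.asarray(tr.window_centers, dtype=float)
        vals = np.asarray(tr.values, dtype=float)
        base = vals[(centers >= t0) & (centers < t1)]
        if base.size < 2:
            raise ValueError("baseline_range covers fewer than 2 windows")
        level = float(base.mean() + 2.0 * base.std(ddof=1))
        pre = centers <= transition_time
        idx = np.where(pre)[0]
        onset_time = None
        lin = None
        comparison = None
        if idx.size >= 3:
            below = vals[idx] <= level
            if below.any() and not below[-1]:
                last_below = idx[np.where(below)[0][-1]]
                seg = slice(last_below, idx[-1] + 1)
                if idx[-1] + 1 - last_below >= 3:
                    onset_time = float(centers[last_below])
                    t_seg, v_seg = centers[seg], vals[seg]
                    slope, intercept = np.polyfit(t_seg, v_seg, 1)
                    lin = {"slope": float(slope), "intercept": float(intercept)}
                    comparison = compare_trend_models(t_seg, v_seg)
        results.append(
            OnsetResult(
                scale_j=tr.scale_j,
                onset_time=onset_time,
                baseline_level=level,
                linear_fit=lin,
                fit_comparison=comparison,
            )
        )
    return results
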