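"""Maximum linear cross-correlation (MLCC) between channel pairs.

The lag-dependent linear cross-correlation of two windows is the Pearson
correlation of their overlapping spans (each span mean-removed and scaled
to unit sample variance).  MLCC is the maximum of its absolute value over
lags in [-max_lag, max_lag] — a linear measure of lag synchronization in
[0, 1] that also captures anti-phase locking.  The windowed variant draws
a fixed random sample of channel pairs once per run and averages the
per-pair MLCC in each sliding window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .wavelet_phase import SynchronyTrace

__all__ = [
    "PairSample",
    "MlccResult",
    "BaselineComparison",
    "cross_correlation_fn",
    "mlcc",
    "windowed_mlcc",
    "baseline_comparison",
    "sample_pairs",
]


@dataclass(frozen=True)
class MlccResult:
    value: float
    lag: int


@dataclass
class PairSample:
    """Unordered distinct channel pairs, frozen for a whole run."""

    pairs: list[tuple[int, int]]
    seed: int | None

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"pair ({i}, {j}) is not distinct")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"pair {key} repeated")
            seen.add(key)


@dataclass
class BaselineComparison:
    """Mean/SD of two synchrony traces over a common span, and the difference."""

    span: tuple[float, float]
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    @property
    def difference(self) -> float:
        return self.mean_a - self.mean_b


def cross_correlation_fn(x, y, lag: int) -> float:
    """Normalized linear cross-correlation of x and y at one lag.

    Positive lag correlates x[t] with y[t + lag]; both overlapping spans
    are mean-removed and scaled to unit sample variance.  A zero-variance
    overlap yields NaN (flagged undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 2:
        raise ValueError("series must have equal length >= 2")
    if abs(lag) >= n:
        raise ValueError("|lag| must be smaller than the series length")
    if lag >= 0:
        a, b = x[: n - lag], y[lag:]
    else:
        a, b = x[-lag:], y[: n + lag]
    sa, sb = a.std(ddof=0), b.std(ddof=0)
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _xcorr_all_lags(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """cross_correlation_fn for all lags in [-max_lag, max_lag], FFT-based.

    Returns an array indexed by lag + max_lag.  Per-lag overlap means and
    variances come from prefix sums; the raw lagged products from a single
    zero-padded FFT cross-correlation.
    """
    n = x.size
    lags = np.arange(-max_lag, max_lag + 1)
    m = sp_fft.next_fast_len(n + max_lag)
    cx = sp_fft.rfft(x, m)
    cy = sp_fft.rfft(y, m)
    cross = sp_fft.irfft(np.conj(cx) * cy, m)  # cross[k] = sum_t x[t] y[t+k]
    prod = np.where(lags >= 0, cross[lags % m], cross[(m + lags) % m])

    c1x = np.concatenate([[0.0], np.cumsum(x)])
    c2x = np.concatenate([[0.0], np.cumsum(x * x)])
    c1y = np.concatenate([[0.0], np.cumsum(y)])
    c2y = np.concatenate([[0.0], np.cumsum(y * y)])
    n_eff = n - np.abs(lags)
    lo_x = np.where(lags >= 0, 0, -lags)
    lo_y = np.where(lags >= 0, lags, 0)
    sx = c1x[lo_x + n_eff] - c1x[lo_x]
    sxx = c2x[lo_x + n_eff] - c2x[lo_x]
    sy = c1y[lo_y + n_eff] - c1y[lo_y]
    syy = c2y[lo_y + n_eff] - c2y[lo_y]
    cov = prod - sx * sy / n_eff
    var_x = sxx - sx * sx / n_eff
    var_y = syy - sy * sy / n_eff
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x * var_y)
    r[(var_x <= 0) | (var_y <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def mlcc(x, y, max_lag: int) -> MlccResult:
    """Maximum of |cross-correlation| over lags in [-max_lag, max_lag].

    Returns the maximum value (in [0, 1]) and the maximizing lag; among
    ties the lag closest to zero wins.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the series length")
    r = _xcorr_all_lags(x, y, max_lag)
    if np.all(np.isnan(r)):
        return MlccResult(value=float("nan"), lag=0)
    absr = np.where(np.isnan(r), -1.0, np.abs(r))
    # stable argmax preferring small |lag|
    order = np.argsort(np.abs(np.arange(-max_lag, max_lag + 1)), kind="stable")
    best = order[np.argmax(absr[order])]
    return MlccResult(value=float(absr[best]), lag=int(best - max_lag))


def sample_pairs(n_channels: int, n_pairs: int, seed: int | None) -> PairSample:
    """Draw ``n_pairs`` distinct unordered channel pairs with a fixed seed."""
    all_pairs = list(itertools.combinations(range(n_channels), 2))
    if n_pairs > len(all_pairs):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds the {len(all_pairs)} distinct pairs "
            f"of {n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return PairSample(pairs=[all_pairs[i] for i in sorted(idx)], seed=seed)


def windowed_mlcc(
    signals,
    n_pairs: int = 5,
    window_len: int = 5000,
    step: int = 50,
    max_lag: int = 100,
    seed: int | None = 0,
    pair_sample: PairSample | None = None,
) -> tuple[SynchronyTrace, PairSample]:
    """Pair-averaged MLCC over sliding windows.

    Channel pairs are drawn once per run (not per window) so consecutive
    windows are comparable; the same seed reproduces the same pairs and
    trace exactly.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n = signals.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if window_len > n:
        raise ValueError(f"series too short: length {n} < window_len {window_len}")
    ps = pair_sample if pair_sample is not None else sample_pairs(n_ch, n_pairs, seed)
    starts = np.arange(0, n - window_len + 1, step)
    values = np.zeros(starts.size)
    for i, k in ps.pairs:
        xi, xk = signals[i], signals[k]
        for w, s in enumerate(starts):
            values[w] += mlcc(xi[s : s + window_len], xk[s : s + window_len], max_lag).value
    values /= len(ps.pairs)
    trace = SynchronyTrace(
        window_centers=starts + window_len // 2, values=values, measure="mlcc"
    )
    return trace, ps


def baseline_comparison(
    trace_a: SynchronyTrace,
    trace_b: SynchronyTrace,
    span: tuple[float, float] = (0, 150_000),
) -> BaselineComparison:
    """Mean and SD of two traces over a sample span, and their difference.

    Typical use: pre-ictal vs inter-ictal synchronization level over the
    first part of each recording.  No hypothesis test is performed; the
    summary reports means with standard deviations only.
    """
    lo, hi = span
    out = []
    for tr in (trace_a, trace_b):
        centers = np.asarray(tr.window_centers, dtype=float)
        if hi > centers.max() + 1:
            raise ValueError(
                f"span {span} not covered by trace ending at {centers.max()}"
            )
        sel = tr.values[(centers >= lo) & (centers < hi)]
        if sel.size < 2:
            raise ValueError("span contains fewer than 2 windows")
        out.append((float(sel.mean()), float(sel.std(ddof=1))))
    return BaselineComparison(
        span=(float(lo), float(hi)),
        mean_a=out[0][0],
        sd_a=out[0][1],
        mean_b=out[1][0],
        sd_b=out[1][1],
    )
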