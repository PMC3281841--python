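"""Sliding-window variance statistics and scaling-law fits.

Near a critical transition the variance of the fast variable carries an
early-warning signature.  Two scaling laws are fitted here:

* approach to a fold along an attracting branch: under a frozen-coefficient
  Ornstein-Uhlenbeck approximation the variance diverges like
  Var(x) = D / (2 (x^2 - 1)) as the branch position x approaches the fold
  at |x| = 1, with D a free constant absorbing the noise level;

* approach to a Hopf bifurcation with linearly drifting parameter: the
  inverse variance decays affinely in time, so an ordinary least-squares
  fit of 1/Var against time extrapolates the transition as the zero
  crossing of the fitted line.

The local-maxima marking reproduces the convention of subdividing a trace
into equal time intervals and accepting an interval's maximum only when it
is also a local maximum of the full series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .sde import SamplePath

__all__ = [
    "VarianceTrace",
    "ScalingFit",
    "MarkedExtrema",
    "sliding_variance",
    "ensemble_variance",
    "fit_fold_variance",
    "fit_inverse_variance_linear",
    "find_marked_maxima",
    "compare_trend_models",
    "trend_statistic",
]


@dataclass
class VarianceTrace:
    """Per-window sample variance of a series (window centers in samples)."""

    window_centers: np.ndarray
    values: np.ndarray
    window_len: int
    step: int

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers)
        self.values = np.asarray(self.values, dtype=float)
        if self.window_centers.shape != self.values.shape:
            raise ValueError("window_centers and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("variance values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.window_centers, self.values])


@dataclass
class ScalingFit:
    """A fitted scaling-law model for a variance trace.

    model is "linear_inverse_variance" (1/Var affine in time; coefficients
    slope and intercept, with the extrapolated zero crossing as
    predicted_transition when the slope is negative) or "fold_pole"
    (Var = D / (2 (x^2 - 1)); coefficient D).
    """

    model: str
    coefficients: dict
    r_squared: float
    fit_range: tuple[int, int]
    predicted_transition: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class MarkedExtrema:
    """Accepted local maxima from the interval-subdivision marking rule."""

    marked_indices: np.ndarray
    n_intervals: int


def _window_starts(n: int, window_len: int, step: int) -> np.ndarray:
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_len > n:
        raise ValueError(
            f"series too short: length {n} < window_len {window_len}"
        )
    return np.arange(0, n - window_len + 1, step)


def _sliding_var_matrix(x: np.ndarray, window_len: int, step: int) -> np.ndarray:
    """Unbiased per-window variance for each row of ``x`` (2D, paths x time)."""
    n = x.shape[-1]
    starts = _window_starts(n, window_len, step)
    x = x - x.mean(axis=-1, keepdims=True)  # shift-invariant; conditions the sums
    c1 = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    c2 = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x * x, axis=-1)], axis=-1
    )
    s1 = c1[..., starts + window_len] - c1[..., starts]
    s2 = c2[..., starts + window_len] - c2[..., starts]
    var = (s2 - s1 * s1 / window_len) / (window_len - 1)
    return np.maximum(var, 0.0)  # guard cumulative-sum round-off


def sliding_variance(series, window_len: int = 5000, step: int = 50) -> VarianceTrace:
    """Unbiased sample variance over sliding windows of the raw series.

    The first window starts at sample 0, consecutive windows are shifted by
    ``step`` samples and a trailing partial window is discarded.  No
    detrending is applied.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    starts = _window_starts(x.size, window_len, step)
    values = _sliding_var_matrix(x[np.newaxis, :], window_len, step)[0]
    return VarianceTrace(starts + window_len // 2, values, window_len, step)


def ensemble_variance(
    paths: Sequence[SamplePath],
    component: int = 0,
    window_len: int = 5000,
    step: int = 50,
) -> VarianceTrace:
    """Sliding-window variance per path, averaged pointwise over the ensemble."""
    if len(paths) == 0:
        raise ValueError("empty path collection")
    n = paths[0].n_steps
    dt = paths[0].dt
    for p in paths:
        if p.n_steps != n or p.dt != dt:
            raise ValueError("paths must share length and dt")
    mat = np.stack([p.component(component) for p in paths])
    starts = _window_starts(n, window_len, step)
    values = _sliding_var_matrix(mat, window_len, step).mean(axis=0)
    return VarianceTrace(starts + window_len // 2, values, window_len, step)


def window_means(series, window_len: int, step: int) -> np.ndarray:
    """Per-window means on the same grid as :func:`sliding_variance`."""
    x = np.asarray(series, dtype=float)
    starts = _window_starts(x.size, window_len, step)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    return (c1[starts + window_len] - c1[starts]) / window_len


def _resolve_range(fit_range, n: int) -> slice:
    if fit_range is None:
        return slice(0, n)
    i0, i1 = fit_range
    if not (0 <= i0 < i1 <= n):
        raise ValueError(f"fit_range {fit_range} out of bounds for {n} windows")
    return slice(i0, i1)


def fit_fold_variance(
    trace: VarianceTrace,
    positions,
    fit_range: tuple[int, int] | None = None,
) -> ScalingFit:
    """Least-squares fit of the fold pole law Var(x) = D / (2 (x^2 - 1)).

    ``positions`` are the per-window means of the fast variable; they must
    all lie on an attracting outer branch (|x| > 1).  The single constant
    D >= 0 is fitted in closed form (the model is linear in D).
    """
    sel = _resolve_range(fit_range, len(trace))
    v = trace.values[sel]
    x = np.asarray(positions, dtype=float)[sel]
    if np.any(np.abs(x) <= 1.0):
        raise ValueError("position off attracting branch: |x| <= 1 in fit range")
    g = 1.0 / (2.0 * (x**2 - 1.0))
    d = max(float(np.dot(v, g) / np.dot(g, g)), 0.0)
    resid = v - d * g
    tss = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    rng = (sel.start, sel.stop)
    return ScalingFit(
        model="fold_pole",
        coefficients={"D": d},
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        fit_range=rng,
    )


def fit_inverse_variance_linear(
    trace: VarianceTrace,
    fit_range: tuple[int, int] | None = None,
) -> ScalingFit:
    """Ordinary least squares of 1/Var against window center.

    When the fitted slope is negative the zero crossing of the line is
    reported as the predicted transition time (in sample units); otherwise
    no prediction is made.
    """
    sel = _resolve_range(fit_range, len(trace))
    v = trace.values[sel]
    if np.any(v <= 0):
        raise ValueError("zero variance in fit range; 1/Var undefined")
    t = np.asarray(trace.window_centers[sel], dtype=float)
    w = 1.0 / v
    slope, intercept = np.polyfit(t, w, 1)
    fitted = slope * t + intercept
    tss = float(np.sum((w - w.mean()) ** 2))
    r2 = 1.0 - float(np.sum((w - fitted) ** 2)) / tss if tss > 0 else 1.0
    predicted = float(-intercept / slope) if slope < 0 else None
    return ScalingFit(
        model="linear_inverse_variance",
        coefficients={"slope": float(slope), "intercept": float(intercept)},
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        fit_range=(sel.start, sel.stop),
        predicted_transition=predicted,
    )


def find_marked_maxima(
    series,
    n_intervals: int = 20,
    neighborhood_radius: int | None = None,
) -> MarkedExtrema:
    """Mark interval maxima that are also local maxima of the full series.

    The series is subdivided into ``n_intervals`` equal index intervals; the
    argmax of each interval is accepted iff it is a strict local maximum of
    the whole series within ``neighborhood_radius`` samples (default: one
    interval width) and does not sit at either edge of the series.  The
    marking is invariant under positive affine rescaling of the values.
    """
    v = np.asarray(series, dtype=float)
    n = v.size
    if n < n_intervals:
        raise ValueError("series shorter than the number of intervals")
    radius = neighborhood_radius if neighborhood_radius is not None else n // n_intervals
    radius = max(radius, 1)
    bounds = (np.arange(n_intervals + 1) * n) // n_intervals
    marked = []
    for k in range(n_intervals):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            continue
        i = lo + int(np.argmax(v[lo:hi]))
        if i == 0 or i == n - 1:
            continue
        a, b = max(0, i - radius), min(n, i + radius + 1)
        neighborhood = v[a:b]
        if np.sum(neighborhood == v[i]) == 1 and v[i] == neighborhood.max():
            marked.append(i)
    return MarkedExtrema(np.asarray(marked, dtype=int), n_intervals)


def trend_statistic(values, segment: tuple[int, int] | None = None) -> float:
    """Spearman rank correlation of a trace segment against time.

    Positive values near +1 indicate a monotone increase, negative values a
    monotone decrease; oscillatory segments give small magnitudes.
    """
    v = np.asarray(values, dtype=float)
    sel = _resolve_range(segment, v.size)
    seg = v[sel]
    rho = stats.spearmanr(np.arange(seg.size), seg).statistic
    return float(rho)


def count_interior_maxima(values, min_prominence_frac: float = 0.05) -> int:
    """Number of interior local maxima with modest prominence.

    Used to assert oscillatory (multi-peaked) variance traces; prominence is
    measured relative to the trace's value range so the count is invariant
    under positive affine rescaling.
    """
    from scipy.signal import find_peaks

    v = np.asarray(values, dtype=float)
    vrange = float(v.max() - v.min())
    if vrange == 0:
        return 0
    peaks, _ = find_peaks(v, prominence=min_prominence_frac * vrange)
    return int(peaks.size)


def _fit_rss(t: np.ndarray, v: np.ndarray, kind: str) -> float:
    """Residual sum of squares of a trend model fitted to (t, v)."""
    s = t - t[0]
    if kind == "linear":
        coef = np.polyfit(s, v, 1)
        return float(np.sum((np.polyval(coef, s) - v) ** 2))
    try:
        if kind == "exponential":
            # v = a * exp(b s); log-linear start, refined by nonlinear LSQ
            if np.all(v > 0):
                b0, loga = np.polyfit(s, np.log(v), 1)
                p0 = (float(np.exp(loga)), float(b0))
            else:
                p0 = (max(float(np.mean(np.abs(v))), 1e-12), 0.0)
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(np.clip(b * x, -700, 700)),
                s, v, p0=p0, maxfev=5000,
            )
            fitted = popt[0] * np.exp(np.clip(popt[1] * s, -700, 700))
        elif kind == "power":
            # v = a * (s + 1)^b
            u = s + 1.0
            if np.all(v > 0):
                b0, loga = np.polyfit(np.log(u), np.log(v), 1)
                p0 = (float(np.exp(loga)), float(b0))
            else:
                p0 = (max(float(np.mean(np.abs(v))), 1e-12), 1.0)
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.power(x + 1.0, b), s, v, p0=p0, maxfev=5000
            )
            fitted = popt[0] * np.power(u, popt[1])
        else:
            raise ValueError(f"unknown model kind {kind!r}")
    except (RuntimeError, TypeError, np.linalg.LinAlgError):
        return float("inf")
    return float(np.sum((fitted - v) ** 2))


def compare_trend_models(t, v) -> dict:
    """Compare linear vs power-law vs exponential fits by residual sum of squares.

    Returns {"rss": {model: rss}, "winner": model}; ties favour the linear
    model (the simplest of the three).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to compare trend models")
    rss = {kind: _fit_rss(t, v, kind) for kind in ("linear", "power", "exponential")}
    winner = "linear"
    for kind in ("power", "exponential"):
        if rss[kind] < rss[winner] - 1e-15 * max(1.0, rss[winner]):
            winner = kind
    return {"rss": rss, "winner": winner}
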