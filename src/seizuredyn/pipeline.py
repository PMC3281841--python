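"""Full three-scale analysis of a multichannel recording.

``run_analysis`` orchestrates, over one recording (real or synthetic):

1. cluster-level early warning — sliding-window variance of the
   channel-average signal, interval-subdivision maxima marking, and the
   linear inverse-variance fit with its extrapolated transition time;
2. lag synchronization — windowed pair-averaged maximum linear
   cross-correlation (MLCC) over a fixed random pair sample;
3. phase synchronization — PLW and windowed mean phase coherence per
   dyadic wavelet scale, and (when a transition time is supplied) the
   per-scale onset of the sustained synchronization rise with a
   linear/power/exponential fit comparison.

The result is a serializable AnalysisReport whose config echo reproduces
the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .crosscorr import baseline_comparison, sample_pairs, windowed_mlcc
from .early_warning import (
    find_marked_maxima,
    fit_inverse_variance_linear,
    sliding_variance,
)
from .recording import TimeSeriesRecording, read_recording, write_recording
from .wavelet_phase import (
    DEFAULT_PHASE_THRESHOLD,
    DEFAULT_SIGNIFICANCE_THRESHOLD,
    SynchronyTrace,
    detect_scale_onsets,
    plw_measure,
    windowed_mpc,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "channel_average",
    "default_scales",
    "run_analysis",
]


def default_scales(fs: float, n_scales: int = 3) -> tuple[int, ...]:
    """Consecutive dyadic scales whose bands best cover roughly 3-32 Hz.

    The first scale is the smallest j with an upper band edge fs/2^j at or
    below 32 Hz; at 256 Hz this yields scales (3, 4, 5) with bands 16-32,
    8-16 and 4-8 Hz, and at 200 Hz the 12.5-25 / 6.25-12.5 / 3.1-6.25 Hz
    set.
    """
    j0 = max(1, math.ceil(math.log2(fs / 32.0)))
    return tuple(range(j0, j0 + n_scales))


@dataclass
class AnalysisConfig:
    """Windowing, scale and threshold conventions for one analysis run.

    Defaults follow the recording-analysis conventions: 5000-sample
    windows shifted by 50 samples, 5 random channel pairs for MLCC, 20
    subdivision intervals for the maxima marking, a pi/4 phase-locking
    threshold with a 0.5 significance gate.  ``transition_time`` (sample
    index) is an externally supplied reference, never auto-detected.
    """

    window_len: int = 5000
    step: int = 50
    scales: tuple[int, ...] | None = None  # None: derived from fs
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
    smoothing_len: int | None = None  # None: 2^j per scale
    n_pairs: int = 5
    max_lag: int | None = None  # None: fs / 2 samples
    n_intervals: int = 20
    fit_range: tuple[int, int] | None = None  # None: last 20% of pre-transition
    baseline_range: tuple[float, float] | None = None  # None: first half
    transition_time: float | None = None
    engine: str = "filter_bank"
    seed: int = 0

    def __post_init__(self):
        if not (self.window_len > self.step > 0):
            raise ValueError("window_len > step > 0 required")
        if not (0 < self.phase_threshold <= np.pi):
            raise ValueError("phase_threshold must lie in (0, pi]")
        if not (0 < self.significance_threshold <= 1):
            raise ValueError("significance_threshold must lie in (0, 1]")

    def resolved(self, fs: float) -> "AnalysisConfig":
        """A copy with fs-dependent defaults (scales, max_lag) filled in."""
        cfg = AnalysisConfig(**asdict(self))
        if cfg.scales is None:
            cfg.scales = default_scales(fs)
        else:
            cfg.scales = tuple(cfg.scales)
        if cfg.max_lag is None:
            cfg.max_lag = max(1, int(fs // 2))
        return cfg


def channel_average(rec: TimeSeriesRecording) -> np.ndarray:
    """Pointwise mean across channels (the cluster-level activity proxy)."""
    return rec.data.mean(axis=0)


def _trace_dict(trace) -> dict:
    d = {
        "window_centers": np.asarray(trace.window_centers).tolist(),
        "values": np.asarray(trace.values).tolist(),
    }
    if getattr(trace, "scale_j", None) is not None:
        d["scale_j"] = trace.scale_j
    return d


@dataclass
class AnalysisReport:
    """Aggregated, serializable result of one analysis run."""

    config: dict
    provenance: dict
    variance: dict
    mlcc: dict
    plw: list[dict]
    mpc: list[dict]
    onsets: list[dict] | None
    timings: dict = field(default_factory=dict)

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(asdict(self), indent=indent)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(indent=1))

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "AnalysisReport":
        return cls.from_json(Path(path).read_text())


def _default_fit_range(centers: np.ndarray, transition_time: float | None):
    """Last 20% of windows preceding the transition (or of all windows)."""
    if transition_time is None:
        idx = np.arange(centers.size)
    else:
        idx = np.where(centers < transition_time)[0]
    if idx.size < 3:
        raise ValueError("too few windows before the transition for a fit")
    return (int(idx[int(0.8 * idx.size)]), int(idx[-1] + 1))


def run_analysis(rec: TimeSeriesRecording, config: AnalysisConfig) -> AnalysisReport:
    """Run the full three-scale analysis; deterministic given (rec, config)."""
    cfg = config.resolved(rec.fs)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    avg = channel_average(rec)
    var_trace = sliding_variance(avg, cfg.window_len, cfg.step)
    centers = np.asarray(var_trace.window_centers, dtype=float)
    marked = find_marked_maxima(var_trace.values, cfg.n_intervals)
    fit_range = cfg.fit_range or _default_fit_range(centers, cfg.transition_time)
    try:
        inv_fit = fit_inverse_variance_linear(var_trace, fit_range)
        inv_fit_dict = {
            "model": inv_fit.model,
            "coefficients": inv_fit.coefficients,
            "r_squared": inv_fit.r_squared,
            "fit_range": list(inv_fit.fit_range),
            "predicted_transition": inv_fit.predicted_transition,
        }
    except ValueError as exc:
        raise RuntimeError(f"early_warning stage failed: {exc}") from exc
    timings["early_warning"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if rec.n_channels >= 2:
        try:
            mlcc_trace, pairs = windowed_mlcc(
                rec.data,
                n_pairs=min(cfg.n_pairs, rec.n_channels * (rec.n_channels - 1) // 2),
                window_len=cfg.window_len,
                step=cfg.step,
                max_lag=cfg.max_lag,
                seed=cfg.seed,
            )
        except ValueError as exc:
            raise RuntimeError(f"cross_correlation stage failed: {exc}") from exc
        mlcc_dict = {"trace": _trace_dict(mlcc_trace), "pairs": pairs.pairs}
    else:
        mlcc_trace = None
        mlcc_dict = {"trace": None, "pairs": []}
    timings["cross_correlation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    plw_traces: list[SynchronyTrace] = []
    mpc_traces: list[SynchronyTrace] = []
    if rec.n_channels >= 2:
        for j in cfg.scales:
            try:
                plw_traces.append(
                    plw_measure(
                        rec.data, rec.fs, j,
                        window_len=cfg.window_len, step=cfg.step,
                        phase_threshold=cfg.phase_threshold,
                        significance_threshold=cfg.significance_threshold,
                        smoothing_len=cfg.smoothing_len, engine=cfg.engine,
                    )
                )
                mpc_traces.append(
                    windowed_mpc(
                        rec.data, rec.fs, j,
                        window_len=cfg.window_len, step=cfg.step,
                        smoothing_len=cfg.smoothing_len, engine=cfg.engine,
                    )
                )
            except ValueError as exc:
                raise RuntimeError(f"wavelet_phase stage failed: {exc}") from exc
    timings["wavelet_phase"] = time.perf_counter() - t0

    onsets = None
    if cfg.transition_time is not None and plw_traces:
        t0 = time.perf_counter()
        baseline = cfg.baseline_range or (0.0, 0.5 * cfg.transition_time)
        try:
            results = detect_scale_onsets(plw_traces, cfg.transition_time, baseline)
        except ValueError as exc:
            raise RuntimeError(f"onset stage failed: {exc}") from exc
        onsets = [
            {
                "scale_j": r.scale_j,
                "onset_time": r.onset_time,
                "baseline_level": r.baseline_level,
                "linear_fit": r.linear_fit,
                "fit_comparison": r.fit_comparison,
            }
            for r in results
        ]
        timings["onsets"] = time.perf_counter() - t0

    digest = hashlib.sha256(np.ascontiguousarray(rec.data).tobytes()).hexdigest()
    cfg_dict = asdict(cfg)
    cfg_dict["scales"] = list(cfg.scales)
    return AnalysisReport(
        config=cfg_dict,
        provenance={
            "input_sha256": digest,
            "n_channels": rec.n_channels,
            "n_samples": rec.n_samples,
            "fs": rec.fs,
            "seed": cfg.seed,
            "version": __version__,
        },
        variance={
            "trace": _trace_dict(var_trace),
            "marked_maxima": marked.marked_indices.tolist(),
            "inverse_fit": inv_fit_dict,
        },
        mlcc=mlcc_dict,
        plw=[_trace_dict(t) for t in plw_traces],
        mpc=[_trace_dict(t) for t in mpc_traces],
        onsets=onsets,
        timings=timings,
    )
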