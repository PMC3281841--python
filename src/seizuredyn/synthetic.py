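"""Synthetic multichannel pre-ictal/inter-ictal recording generator.

Real pre-seizure ECoG is characterized by (a) a variance whose inverse
decays roughly linearly toward the seizure time while oscillating on the
way, (b) band-specific phase coupling between channels that ramps up
linearly starting at different times per frequency band, (c) a *lower*
pre-ictal than inter-ictal synchronization baseline, and (d) broadband
background noise.  This generator produces channels with exactly that
statistical structure — together with the hidden ground truth (seizure
time, per-band coupling onsets and slopes) — so every stage of the
analysis pipeline can be validated by parameter recovery instead of by
eye.

Construction per channel i:

    x_i(t) = sum_b a_b w_ib cos(phi_ib(t)) + g E(t) eta_i(t) + pink + white

where phi_ib(t) mixes a shared band phase with a per-channel stationary
phase-wander process, time-multiplexed by recurring synchronization
episodes whose duty cycle equals the coupling
c_b(t) = clip(baseline + slope * max(0, t - t_b), 0, 1), so the pair-time
locked fraction is linear in the coupling.  E(t) is the smoothed root-mean-square fast-pair
amplitude of a small ensemble of driven subcritical Hopf paths whose slow
parameter crosses zero at the seizure time t_c, so the channel variance grows like 1/(t_c - t) and the inverse
variance of the channel average decays linearly.  Inter-ictal mode uses a
constant (higher) coupling, no ramps and a flat envelope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .recording import TimeSeriesRecording
from .sde import HopfParameters, simulate_hopf_ensemble
from .wavelet_phase import scale_band

__all__ = ["BandSpec", "SyntheticSpec", "GroundTruth", "generate_recording", "make_fixture"]

FIXTURE_NAMES = ("tiny", "preictal_default", "interictal_default")


@dataclass(frozen=True)
class BandSpec:
    """One dyadic-band oscillatory component and its coupling schedule."""

    scale_j: int
    coupling_onset: int  # t_b, sample index at which the ramp starts
    baseline_coupling: float
    ramp_slope: float  # coupling increase per sample after onset
    amplitude: float = 1.0


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic recording.

    ``mode`` is "preictal" (coupling ramps toward the seizure at t_c and a
    Hopf-driven variance envelope) or "interictal" (constant coupling, no
    transition).  ``phase_wander_sd`` (radians) sets the channel phase
    spread at zero coupling; ``hopf_gain`` scales the variance envelope
    relative to unit baseline.
    """

    n_channels: int = 8
    fs: float = 256.0
    duration: int = 230_000
    seizure_time: int = 215_000
    band_specs: list[BandSpec] = field(default_factory=list)
    noise_white_sd: float = 0.3
    pink_amplitude: float = 0.3
    phase_wander_sd: float = 2.5
    phase_wander_tau: float = 64.0  # samples
    hopf_gain: float = 1.0
    hopf_sigma: float = 0.01
    envelope_cutoff_hz: float | None = None  # None: below the lowest band
    weight_jitter: float = 0.2  # half-width of the per-channel band weights
    gate_period: int = 1000  # samples; recurrence of synchronization episodes
    mode: str = "preictal"
    seed: int | None = 0

    def __post_init__(self):
        if self.mode not in ("preictal", "interictal"):
            raise ValueError("mode must be 'preictal' or 'interictal'")
        if self.n_channels < 1 or self.fs <= 0 or self.duration < 1:
            raise ValueError("invalid channel count, fs, or duration")
        if self.mode == "preictal" and not (0 < self.seizure_time <= self.duration):
            raise ValueError("seizure_time must lie in (0, duration]")
        for b in self.band_specs:
            if self.mode == "preictal" and not (0 < b.coupling_onset < self.seizure_time):
                raise ValueError(
                    f"band onset {b.coupling_onset} must lie in (0, seizure_time)"
                )
            if not (0.0 <= b.baseline_coupling <= 1.0):
                raise ValueError("baseline_coupling must lie in [0, 1]")
            if b.ramp_slope < 0:
                raise ValueError("ramp_slope must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["band_specs"] = [asdict(b) for b in self.band_specs]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        d["band_specs"] = [BandSpec(**b) for b in d["band_specs"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Hidden truth serialized with every generated recording."""

    seizure_time: int | None
    band_onsets: dict[int, int]  # scale_j -> sample index
    band_slopes: dict[int, float]
    mixing_weights: np.ndarray  # channels x bands
    coupling_stride: int
    coupling_trajectories: dict[int, np.ndarray]  # scale_j -> subsampled c_b(t)
    envelope_stride: int
    envelope: np.ndarray  # subsampled variance envelope E(t)

    def save(self, path) -> None:
        d = {
            "seizure_time": self.seizure_time,
            "band_onsets": {str(k): v for k, v in self.band_onsets.items()},
            "band_slopes": {str(k): v for k, v in self.band_slopes.items()},
            "mixing_weights": self.mixing_weights.tolist(),
            "coupling_stride": self.coupling_stride,
            "coupling_trajectories": {
                str(k): v.tolist() for k, v in self.coupling_trajectories.items()
            },
            "envelope_stride": self.envelope_stride,
            "envelope": self.envelope.tolist(),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seizure_time=d["seizure_time"],
            band_onsets={int(k): v for k, v in d["band_onsets"].items()},
            band_slopes={int(k): v for k, v in d["band_slopes"].items()},
            mixing_weights=np.asarray(d["mixing_weights"]),
            coupling_stride=d["coupling_stride"],
            coupling_trajectories={
                int(k): np.asarray(v) for k, v in d["coupling_trajectories"].items()
            },
            envelope_stride=d["envelope_stride"],
            envelope=np.asarray(d["envelope"]),
        )


def _ar1(rng: np.random.Generator, shape: tuple, sd: float, tau: float) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein-Uhlenbeck) noise along the last axis."""
    rho = np.exp(-1.0 / tau)
    innov = rng.standard_normal(shape) * sd * np.sqrt(1.0 - rho**2)
    innov[..., 0] = rng.standard_normal(shape[:-1]) * sd
    return lfilter([1.0], [1.0, -rho], innov, axis=-1)


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, rms: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, normalized per channel to the given rms."""
    if rms == 0:
        return np.zeros((n_channels, n))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * shape, n, axis=-1)
    scale = pink.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return pink / scale * rms


def _hopf_envelope(spec: SyntheticSpec, seed) -> np.ndarray:
    """Variance envelope from a driven Hopf fast-pair amplitude.

    The slow parameter runs from -1 toward 0, reaching it at the seizure
    time; the simulation is stopped shortly before the crossing (the
    subcritical escape would diverge) and the last value is held.  The
    smoothed amplitude is normalized to unit initial level so hopf_gain
    sets the baseline contribution directly.
    """
    t_c = spec.seizure_time
    dt = 1.0 / spec.fs
    y_stop = -0.02
    n_sim = int(t_c * (1.0 + y_stop))
    eps = spec.fs / t_c  # |y0| = 1 crossed after t_c samples
    params = HopfParameters(
        epsilon=eps, sigma=spec.hopf_sigma, y0=-1.0, x0=(0.05, 0.0),
        dt=dt, n_steps=max(n_sim, 2),
    )
    # Average the squared fast amplitude over a small path ensemble (the
    # single-path amplitude is exponentially dispersed near the transition,
    # which would bury the mean 1/|y| growth this envelope must carry).
    paths = simulate_hopf_ensemble(params, n_paths=32, seed=seed)
    r2 = np.mean([p.states[0] ** 2 + p.states[1] ** 2 for p in paths], axis=0)
    # smoothing span: ~4 s, but never more than ~1.5% of the approach (short
    # recordings would otherwise smooth away the late growth entirely)
    k = max(int(min(4 * spec.fs, t_c / 64)) | 1, 3)
    kernel = np.ones(k) / k
    smooth = np.sqrt(np.maximum(np.convolve(r2, kernel, mode="same"), 0.0))
    baseline = smooth[: max(len(smooth) // 10, 1)].mean()
    env = smooth / max(baseline, 1e-12)
    out = np.empty(spec.duration)
    m = min(len(env), spec.duration)
    out[:m] = env[:m]
    if m < spec.duration:
        # continue the mean-square 1/(t_c - t) growth over the unsimulated
        # tail (capped), then hold through and past the transition
        tail = np.arange(m, spec.duration, dtype=float)
        growth = np.sqrt((t_c - (m - 1)) / np.maximum(t_c - tail, t_c * 0.005))
        out[m:] = env[m - 1] * np.minimum(growth, 3.0)
    return out


def coupling_trajectory(spec: SyntheticSpec, band: BandSpec) -> np.ndarray:
    """c_b(t) over the full duration, clipped to [0, 1]."""
    t = np.arange(spec.duration, dtype=float)
    if spec.mode == "interictal":
        return np.full(spec.duration, band.baseline_coupling)
    ramp = band.ramp_slope * np.maximum(0.0, t - band.coupling_onset)
    return np.clip(band.baseline_coupling + ramp, 0.0, 1.0)


def generate_recording(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Generate a recording and its ground truth from a validated spec.

    Identical (spec, seed) yield bit-identical output.  When ``seed`` is
    omitted the spec's own seed field is used.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n, n_ch = spec.duration, spec.n_channels
    t = np.arange(n, dtype=float)
    data = np.zeros((n_ch, n))

    weights = np.ones((n_ch, len(spec.band_specs)))
    couplings = {}
    for bi, band in enumerate(spec.band_specs):
        f_lo, f_hi = scale_band(spec.fs, band.scale_j)
        f_b = np.sqrt(f_lo * f_hi)  # geometric band center
        c = coupling_trajectory(spec, band)
        couplings[band.scale_j] = c
        # shared source phase: band-center tone + slow common wander
        common = _ar1(rng, (n,), sd=0.3, tau=4 * spec.phase_wander_tau)
        phi_common = 2 * np.pi * f_b * t / spec.fs + common
        wander = _ar1(
            rng, (n_ch, n), sd=spec.phase_wander_sd, tau=spec.phase_wander_tau
        )
        w = 1.0 + rng.uniform(-spec.weight_jitter, spec.weight_jitter, size=n_ch)
        weights[:, bi] = w
        # Time-multiplexed mixing: synchronization episodes recur with a
        # fixed period and a duty cycle equal to c(t), so the pair-time
        # locked fraction is linear in the coupling (an amplitude-scaled
        # mix gives a sigmoidal, saturating response instead).  Episode
        # starts are offset per band; edges are lightly smoothed.  The
        # period divides the analysis window convention (5000 samples),
        # so windowed locking fractions carry no duty-cycle ripple.
        period = spec.gate_period
        offset = int(rng.integers(period))
        gate = (((t.astype(int) + offset) % period) < np.round(c * period)).astype(float)
        gk = np.ones(33)
        gate = np.convolve(gate, gk, mode="same") / np.convolve(
            np.ones(n), gk, mode="same"
        )
        phase = phi_common[np.newaxis, :] + (1.0 - gate)[np.newaxis, :] * wander
        data += band.amplitude * w[:, np.newaxis] * np.cos(phase)

    if spec.mode == "preictal":
        env = _hopf_envelope(spec, seed=rng.integers(2**31))
    else:
        env = np.ones(n)
    if spec.hopf_gain > 0:
        # Envelope-modulated noise carries the variance growth; it is kept
        # below the analysis bands so it does not dilute their phase
        # coherence (in real seizures the growing power is itself coherent;
        # here coherence is controlled solely by the coupling ramps).
        cutoff = spec.envelope_cutoff_hz
        if cutoff is None and spec.band_specs:
            # half the lowest band edge: the analysis filter bank's skirt
            # reaches below the nominal band, and the late envelope power is
            # large enough for even -20 dB leakage to dilute band locking
            cutoff = 0.5 * min(
                scale_band(spec.fs, b.scale_j)[0] for b in spec.band_specs
            )
        carrier = rng.standard_normal((n_ch, n))
        if cutoff is not None and cutoff < spec.fs / 2:
            spec_c = np.fft.rfft(carrier, axis=-1)
            spec_c[:, np.fft.rfftfreq(n, d=1.0 / spec.fs) > cutoff] = 0.0
            carrier = np.fft.irfft(spec_c, n, axis=-1)
            carrier /= carrier.std(axis=-1, keepdims=True)
        data += spec.hopf_gain * env[np.newaxis, :] * carrier

    data += _pink_noise(rng, n_ch, n, spec.pink_amplitude)
    if spec.noise_white_sd > 0:
        data += spec.noise_white_sd * rng.standard_normal((n_ch, n))

    stride = 500
    truth = GroundTruth(
        seizure_time=spec.seizure_time if spec.mode == "preictal" else None,
        band_onsets={
            b.scale_j: (b.coupling_onset if spec.mode == "preictal" else 0)
            for b in spec.band_specs
        },
        band_slopes={
            b.scale_j: (b.ramp_slope if spec.mode == "preictal" else 0.0)
            for b in spec.band_specs
        },
        mixing_weights=weights,
        coupling_stride=stride,
        coupling_trajectories={j: c[::stride].copy() for j, c in couplings.items()},
        envelope_stride=stride,
        envelope=env[::stride].copy(),
    )
    rec = TimeSeriesRecording(
        channel_names=[f"ch{i + 1}" for i in range(n_ch)],
        data=data,
        fs=spec.fs,
    )
    return rec, truth


def _fixture_spec(name: str) -> SyntheticSpec:
    if name == "tiny":
        return SyntheticSpec(
            n_channels=4,
            fs=256.0,
            duration=30_000,
            seizure_time=26_000,
            band_specs=[
                BandSpec(3, 10_000, 0.2, 0.45 / 16_000),
                BandSpec(4, 14_000, 0.2, 0.45 / 12_000),
                BandSpec(5, 18_000, 0.2, 0.45 / 8_000),
            ],
        )
    if name == "preictal_default":
        return SyntheticSpec(
            n_channels=8,
            fs=256.0,
            duration=230_000,
            seizure_time=215_000,
            band_specs=[
                BandSpec(3, 140_000, 0.2, 0.45 / 75_000),
                BandSpec(4, 165_000, 0.2, 0.45 / 50_000),
                BandSpec(5, 190_000, 0.2, 0.45 / 25_000),
            ],
        )
    if name == "interictal_default":
        return SyntheticSpec(
            n_channels=8,
            fs=256.0,
            duration=230_000,
            seizure_time=230_000,
            band_specs=[
                BandSpec(3, 1, 0.5, 0.0),
                BandSpec(4, 1, 0.5, 0.0),
                BandSpec(5, 1, 0.5, 0.0),
            ],
            mode="interictal",
        )
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


def make_fixture(
    name: str, seed: int | None = None
) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Generate one of the canned study recordings.

    ``tiny`` is a 4-channel, 30k-sample recording for fast tests;
    ``preictal_default`` is the 8-channel pre-ictal study condition with
    three coupling ramps at scales 3, 4, 5 whose onsets are staggered
    (higher-frequency band first) ahead of the transition;
    ``interictal_default`` is the matched no-transition control with a
    higher constant coupling.
    """
    spec = _fixture_spec(name)
    return generate_recording(spec, seed=seed)


def fixture_spec(name: str) -> SyntheticSpec:
    """The SyntheticSpec behind a named fixture (inspectable and editable)."""
    return _fixture_spec(name)
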