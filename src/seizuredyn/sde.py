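"""Stochastic fast-slow models of excitable neural dynamics.

Two models are provided, both integrated with a fixed-step Euler-Maruyama
scheme:

* a Van-der-Pol-type FitzHugh-Nagumo (FHN) neuron with white noise on the
  fast voltage variable,

      dx = (x - x^3/3 - y + s) dt + sigma dW
      dy = eps (x + a - b y) dt

  whose fast nullcline (the *critical manifold*) is the cubic
  y = x - x^3/3 + s with fold points at x = -1 and x = +1; and

* the normal form of a subcritical Hopf bifurcation with a slowly drifting
  bifurcation parameter,

      dx1 = (y x1 - x2 + x1 (x1^2 + x2^2)) dt + sigma dW1
      dx2 = (x1 + y x2 + x2 (x1^2 + x2^2)) dt + sigma dW2
      dy  = eps dt

  so that the slow variable y is exactly affine in time and crosses the
  bifurcation at y = 0.

The module also exposes the fast-slow geometry (critical manifold, folds,
branch stability, regime classification) that the early-warning analysis
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FhnParameters",
    "HopfParameters",
    "SamplePath",
    "SimulationBlowupError",
    "FoldPointError",
    "euler_maruyama",
    "simulate_fhn",
    "simulate_fhn_ensemble",
    "simulate_hopf",
    "simulate_hopf_ensemble",
    "critical_manifold_y",
    "fold_points",
    "classify_branch",
    "classify_regime",
    "fhn_equilibrium",
    "fhn_input_for_equilibrium",
    "RegimeClassification",
]

# Norm beyond which a trajectory is treated as having escaped to infinity
# (the subcritical Hopf escape diverges in finite time).
_BLOWUP_NORM = 1e8


class SimulationBlowupError(RuntimeError):
    """Raised when a sample path leaves the finite domain.

    Carries ``step`` (the first offending step index) and ``path`` (the
    portion of the trajectory computed before the blow-up).
    """

    def __init__(self, step: int, path: "SamplePath | None" = None):
        super().__init__(
            f"non-finite or exploding state at step {step}; "
            "shrink dt or request truncation"
        )
        self.step = step
        self.path = path


class FoldPointError(ValueError):
    """Raised when a fast-subsystem branch query lands exactly on a fold."""


@dataclass(frozen=True)
class FhnParameters:
    """Parameters of the stochastic Van-der-Pol-type FHN model.

    epsilon    time-scale separation, 0 < epsilon << 1
    input_s    applied current / external signal
    recovery_a, recovery_b
               coefficients of the linear recovery equation
    sigma      white-noise amplitude on the fast variable (>= 0)
    """

    epsilon: float = 0.01
    input_s: float = 0.0
    recovery_a: float = 0.7
    recovery_b: float = 0.8
    sigma: float = 0.0

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class HopfParameters:
    """Parameters of the slowly driven subcritical Hopf normal form.

    epsilon   drift rate of the bifurcation parameter y (per unit time)
    sigma     noise amplitude on each fast component
    y0        initial bifurcation parameter, must be < 0 (pre-transition)
    x0        initial fast state (pair)
    dt        integration step
    n_steps   path length in samples
    """

    epsilon: float = 0.01
    sigma: float = 0.01
    y0: float = -1.0
    x0: tuple[float, float] = (0.0, 0.0)
    dt: float = 1e-3
    n_steps: int = 100_000

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.y0 < 0:
            raise ValueError("y0 must be negative (start before the transition)")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class SamplePath:
    """A uniformly sampled SDE trajectory (state dimension x n samples)."""

    times: np.ndarray
    states: np.ndarray
    dt: float
    seed: int | None = None
    truncated: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[1] != self.times.shape[0]:
            raise ValueError("states and times length mismatch")
        if self.times.size > 1:
            spacing = np.diff(self.times)
            if not np.allclose(spacing, self.dt, rtol=1e-9, atol=1e-12):
                raise ValueError("times must be uniformly spaced by dt")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite entries")

    @property
    def n_steps(self) -> int:
        return self.times.shape[0]

    @property
    def dim(self) -> int:
        return self.states.shape[0]

    def component(self, i: int) -> np.ndarray:
        return self.states[i]

    def to_array(self) -> np.ndarray:
        """Columnar (time, state...) array, one row per sample."""
        return np.column_stack([self.times, self.states.T])

    def save_txt(self, path, state_names: Sequence[str] | None = None) -> None:
        names = state_names or [f"x{i}" for i in range(self.dim)]
        header = "\t".join(["time", *names])
        np.savetxt(path, self.to_array(), delimiter="\t", header=header, comments="")


def _ensemble_euler_maruyama(
    drift: Callable[[np.ndarray], np.ndarray],
    noise_amplitudes: np.ndarray,
    initial_state: np.ndarray,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    on_blowup: str = "raise",
) -> tuple[np.ndarray, bool]:
    """Integrate an ensemble of paths; state arrays have shape (dim, m).

    Returns (states of shape (dim, m, n_kept), truncated_flag).  The noise
    increments are independent Gaussians of variance dt scaled per component.
    On blow-up ``on_blowup`` selects whether to raise or to return the path
    up to the last finite state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    init = np.atleast_2d(np.asarray(initial_state, dtype=float))
    if init.shape[1] == 1 and init.shape[0] > 1 and init.ndim == 2:
        pass
    dim, m = init.shape
    amps = np.asarray(noise_amplitudes, dtype=float).reshape(dim, 1)
    sqrt_dt = np.sqrt(dt)
    out = np.empty((dim, m, n_steps), dtype=float)
    out[:, :, 0] = init
    state = init.copy()
    for k in range(1, n_steps):
        dW = rng.standard_normal((dim, m)) * sqrt_dt
        state = state + drift(state) * dt + amps * dW
        bad = ~np.isfinite(state)
        if bad.any() or np.abs(state[np.isfinite(state)]).max(initial=0.0) > _BLOWUP_NORM:
            if on_blowup == "truncate":
                return out[:, :, :k], True
            raise SimulationBlowupError(k)
        out[:, :, k] = state
    return out, False


def euler_maruyama(
    drift: Callable[[np.ndarray], np.ndarray],
    noise_amplitudes: Sequence[float],
    initial_state: Sequence[float],
    dt: float,
    n_steps: int,
    seed: int | None = None,
    on_blowup: str = "raise",
) -> SamplePath:
    """Fixed-step Euler-Maruyama integration of ``dX = drift(X) dt + A dW``.

    ``drift`` maps a state array of shape (dim, ...) to its time derivative;
    ``noise_amplitudes`` gives one amplitude per component (delta-correlated
    white noise).  Identical (inputs, seed) produce bit-identical paths.
    With ``on_blowup="truncate"`` a diverging path is returned up to its
    last finite state and flagged, instead of raising.
    """
    rng = np.random.default_rng(seed)
    init = np.asarray(initial_state, dtype=float).reshape(-1, 1)
    states, truncated = _ensemble_euler_maruyama(
        drift, noise_amplitudes, init, dt, n_steps, rng, on_blowup=on_blowup
    )
    n = states.shape[2]
    return SamplePath(
        times=np.arange(n) * dt,
        states=states[:, 0, :],
        dt=dt,
        seed=seed,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo
# ---------------------------------------------------------------------------

def fhn_drift(params: FhnParameters) -> Callable[[np.ndarray], np.ndarray]:
    """Drift field of the Van-der-Pol-type FHN model (fast time scale)."""

    def f(state: np.ndarray) -> np.ndarray:
        x, y = state[0], state[1]
        dx = x - x**3 / 3.0 - y + params.input_s
        dy = params.epsilon * (x + params.recovery_a - params.recovery_b * y)
        return np.stack([dx, dy])

    return f


def simulate_fhn(
    params: FhnParameters,
    initial_state: Sequence[float],
    dt: float = 1e-3,
    n_steps: int = 100_000,
    seed: int | None = None,
) -> SamplePath:
    """Simulate the stochastic FHN model; noise acts on the fast variable only."""
    return euler_maruyama(
        fhn_drift(params),
        noise_amplitudes=[params.sigma, 0.0],
        initial_state=initial_state,
        dt=dt,
        n_steps=n_steps,
        seed=seed,
    )


def simulate_fhn_ensemble(
    params: FhnParameters,
    initial_state: Sequence[float],
    dt: float,
    n_steps: int,
    n_paths: int,
    seed: int | None = None,
) -> list[SamplePath]:
    """Simulate ``n_paths`` independent FHN paths from a common start.

    All paths are advanced in lock-step from a single seeded generator, so
    the whole ensemble is reproducible from one seed.
    """
    rng = np.random.default_rng(seed)
    init = np.tile(np.asarray(initial_state, dtype=float).reshape(-1, 1), (1, n_paths))
    states, _ = _ensemble_euler_maruyama(
        fhn_drift(params), [params.sigma, 0.0], init, dt, n_steps, rng
    )
    times = np.arange(states.shape[2]) * dt
    return [
        SamplePath(times=times, states=states[:, i, :], dt=dt, seed=seed)
        for i in range(n_paths)
    ]


def critical_manifold_y(x, input_s: float = 0.0):
    """y-value of the critical manifold (fast nullcline) at abscissa x."""
    x = np.asarray(x, dtype=float)
    out = x - x**3 / 3.0 + input_s
    return out.item() if out.ndim == 0 else out


def fold_points() -> tuple[float, float]:
    """Abscissae of the two fold (saddle-node) points of the fast subsystem."""
    return (-1.0, 1.0)


def classify_branch(x: float) -> str:
    """Classify a point on the critical manifold by fast-flow stability.

    The x-derivative of the fast drift is 1 - x^2: negative means the branch
    attracts the fast flow (refractory branch on the left, excited branch on
    the right), positive means it repels.  Exactly at a fold the fast
    subsystem is not hyperbolic and no classification exists.
    """
    if abs(abs(x) - 1.0) < 1e-12:
        raise FoldPointError(f"x={x} is a fold point, not hyperbolic")
    if x < -1.0:
        return "attracting_left"
    if x > 1.0:
        return "attracting_right"
    return "repelling_middle"


def fhn_equilibrium(params: FhnParameters) -> tuple[float, float]:
    """Global equilibrium of the deterministic FHN system.

    Solves the intersection of the critical manifold with the recovery
    nullcline y = (x + a) / b.  For b < 1 the intersection is unique; a
    multi-equilibrium configuration raises.
    """
    a, b, s = params.recovery_a, params.recovery_b, params.input_s
    # x - x^3/3 + s = (x + a)/b  <=>  x^3 + (3/b - 3) x + (3a/b - 3s) = 0
    roots = np.roots([1.0, 0.0, 3.0 / b - 3.0, 3.0 * a / b - 3.0 * s])
    real = np.real(roots[np.abs(np.imag(roots)) < 1e-9])
    real = np.unique(np.round(real, 12))
    if real.size != 1:
        raise ValueError(
            f"system has {real.size} equilibria; regime classification "
            "assumes a unique global equilibrium"
        )
    x_eq = float(real[0])
    return x_eq, float((x_eq + a) / b)


def fhn_input_for_equilibrium(
    x_eq: float, recovery_a: float = 0.7, recovery_b: float = 0.8
) -> float:
    """Input current s placing the global equilibrium at abscissa ``x_eq``."""
    return (x_eq + recovery_a) / recovery_b - x_eq + x_eq**3 / 3.0


@dataclass(frozen=True)
class RegimeClassification:
    regime: str  # "relaxation" | "excitable"
    equilibrium: tuple[float, float]
    near_fold: bool


def classify_regime(
    params: FhnParameters, fold_tolerance: float = 0.01
) -> RegimeClassification:
    """Relaxation-oscillation vs excitable regime of the FHN model.

    The system is *excitable* when the global equilibrium sits on an
    attracting outer branch (perturbations trigger at most one spike before
    return), and in the *relaxation* regime when it sits on the repelling
    middle branch (a stable periodic orbit surrounds it).  An equilibrium
    within ``fold_tolerance`` of a fold abscissa is flagged degenerate but
    still classified (the boundary itself counts as excitable).
    """
    x_eq, y_eq = fhn_equilibrium(params)
    near_fold = abs(abs(x_eq) - 1.0) <= fold_tolerance
    regime = "excitable" if abs(x_eq) >= 1.0 else "relaxation"
    return RegimeClassification(regime=regime, equilibrium=(x_eq, y_eq), near_fold=near_fold)


# ---------------------------------------------------------------------------
# Hopf normal form
# ---------------------------------------------------------------------------

def hopf_drift(epsilon: float) -> Callable[[np.ndarray], np.ndarray]:
    """Drift of the subcritical Hopf normal form with unit rotation."""
    def f(state: np.ndarray) -> np.ndarray:
        x1, x2, y = state[0], state[1], state[2]
        r2 = x1**2 + x2**2
        dy = np.full_like(np.asarray(y, dtype=float), epsilon)
        return np.stack([y * x1 - x2 + x1 * r2, x1 + y * x2 + x2 * r2, dy])

    return f


def simulate_hopf(
    params: HopfParameters,
    seed: int | None = None,
    on_blowup: str = "truncate",
) -> SamplePath:
    """Simulate the driven subcritical Hopf model.

    Noise acts on the two fast components only, so y(t) = y0 + epsilon * t
    holds exactly along the path.  The escape past the subcritical
    bifurcation diverges in finite time; by default the path up to the last
    finite state is returned and flagged truncated.
    """
    init = [params.x0[0], params.x0[1], params.y0]
    return euler_maruyama(
        hopf_drift(params.epsilon),
        noise_amplitudes=[params.sigma, params.sigma, 0.0],
        initial_state=init,
        dt=params.dt,
        n_steps=params.n_steps,
        seed=seed,
        on_blowup=on_blowup,
    )


def simulate_hopf_ensemble(
    params: HopfParameters,
    n_paths: int,
    seed: int | None = None,
) -> list[SamplePath]:
    """Independent Hopf paths from one seed, truncated at the first blow-up.

    Paths are advanced in lock-step; if any member escapes, the whole
    ensemble is truncated at that step so all returned paths share a grid.
    """
    rng = np.random.default_rng(seed)
    init = np.tile(
        np.asarray([params.x0[0], params.x0[1], params.y0], dtype=float).reshape(-1, 1),
        (1, n_paths),
    )
    states, truncated = _ensemble_euler_maruyama(
        hopf_drift(params.epsilon),
        [params.sigma, params.sigma, 0.0],
        init,
        params.dt,
        params.n_steps,
        rng,
        on_blowup="truncate",
    )
    times = np.arange(states.shape[2]) * params.dt
    return [
        SamplePath(times=times, states=states[:, i, :], dt=params.dt, seed=seed,
                   truncated=truncated)
        for i in range(n_paths)
    ]
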