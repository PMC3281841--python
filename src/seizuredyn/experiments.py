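"""Frozen model-study configurations for the early-warning scaling laws.

These functions bundle the simulation ensembles, windowing and fit ranges
used to demonstrate the three model-level results:

* fold approach (relaxation oscillation): variance along the attracting
  branch follows the pole law Var(x) = D / (2 (x^2 - 1)) and rises
  monotonically toward the jump;
* three excitable-noise regimes: ensemble variance decreases at very
  small noise (metastable trapping), oscillates at intermediate noise
  (ringing of the near-fold focus plus sporadic escapes), and increases
  at larger noise (noise-induced escapes regularize the variance);
* Hopf approach: the inverse variance of the fast variable decays
  affinely in time and its zero crossing estimates the transition.

All parameters are fixed here — seeds are the only inputs — so tests and
reproduction scripts exercise identical study conditions.  Problem sizes
(ensemble counts, horizons, windows) are given in each docstring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .early_warning import (
    compare_trend_models,
    count_interior_maxima,
    ensemble_variance,
    fit_fold_variance,
    fit_inverse_variance_linear,
    sliding_variance,
    trend_statistic,
    window_means,
)
from .sde import (
    FhnParameters,
    HopfParameters,
    critical_manifold_y,
    fhn_input_for_equilibrium,
    simulate_fhn_ensemble,
    simulate_hopf_ensemble,
)

__all__ = [
    "FoldApproachResult",
    "RegimeResult",
    "HopfRecoveryResult",
    "fold_approach_experiment",
    "excitable_regimes_experiment",
    "hopf_recovery_experiment",
    "EXCITABLE_SIGMAS",
]

# Noise triplet for the excitable regimes: (very small, intermediate, large).
EXCITABLE_SIGMAS = (0.001, 0.01, 0.05)


@dataclass
class FoldApproachResult:
    r_squared: float
    diffusion_constant: float
    trend_rho: float
    n_windows: int


def fold_approach_experiment(
    seed: int = 0,
    n_paths: int = 100,
    window_len: int = 5000,
    step: int = 100,
) -> FoldApproachResult:
    """Relaxation-regime fold approach and pole-law fit.

    Simulates ``n_paths`` FHN paths (eps=0.01, sigma=0.01, input placing
    the equilibrium at x=0 so no equilibrium blocks the branch) from
    x=-2 on the critical manifold for 150k steps at dt=1e-3; fits
    Var(x) = D/(2(x^2-1)) over ensemble windows whose mean position lies
    in [-1.8, -1.05] (start transient and fold/jump mixing excluded).
    """
    params = FhnParameters(epsilon=0.01, input_s=0.875, sigma=0.01)
    x0 = -2.0
    y0 = critical_manifold_y(x0, params.input_s)
    paths = simulate_fhn_ensemble(params, [x0, y0], 1e-3, 150_000, n_paths, seed=seed)
    trace = ensemble_variance(paths, 0, window_len, step)
    pos = np.mean([window_means(p.states[0], window_len, step) for p in paths], axis=0)
    sel = np.where((pos >= -1.8) & (pos <= -1.05))[0]
    rng = (int(sel[0]), int(sel[-1] + 1))
    fit = fit_fold_variance(trace, pos, rng)
    rho = trend_statistic(trace.values, rng)
    return FoldApproachResult(
        r_squared=fit.r_squared,
        diffusion_constant=fit.coefficients["D"],
        trend_rho=rho,
        n_windows=rng[1] - rng[0],
    )


@dataclass
class RegimeResult:
    sigma: float
    trend_rho_full: float
    trend_rho_first_half: float
    n_prominent_maxima: int


def excitable_regimes_experiment(
    seed: int = 0,
    n_paths: int = 100,
    n_steps: int = 300_000,
    window_len: int = 5000,
    step: int = 500,
) -> dict[float, RegimeResult]:
    """Ensemble variance in the excitable regime for the noise triplet.

    The equilibrium sits near the left fold (x = -1.02); paths start on
    the branch at x = -1.5 and slide into the focus.  For each sigma in
    EXCITABLE_SIGMAS the ensemble variance trace is summarized by its
    Spearman trend (full horizon and first half) and its count of
    interior maxima with >= 10% prominence.
    """
    s = fhn_input_for_equilibrium(-1.02)
    x0 = -1.5
    y0 = critical_manifold_y(x0, s)
    out = {}
    for k, sigma in enumerate(EXCITABLE_SIGMAS):
        params = FhnParameters(epsilon=0.01, input_s=s, sigma=sigma)
        paths = simulate_fhn_ensemble(
            params, [x0, y0], 1e-3, n_steps, n_paths, seed=seed + k
        )
        trace = ensemble_variance(paths, 0, window_len, step)
        n = len(trace)
        out[sigma] = RegimeResult(
            sigma=sigma,
            trend_rho_full=trend_statistic(trace.values),
            trend_rho_first_half=trend_statistic(trace.values, (0, n // 2)),
            n_prominent_maxima=count_interior_maxima(trace.values, 0.10),
        )
    return out


@dataclass
class HopfRecoveryResult:
    predictions: np.ndarray  # predicted transition times (time units)
    true_transition: float
    median_abs_error: float  # fraction of the approach duration
    model_rss: dict
    model_winner: str


def hopf_recovery_experiment(seed: int = 0, n_runs: int = 20) -> HopfRecoveryResult:
    """Transition-time recovery from the linear inverse-variance law.

    ``n_runs`` independent Hopf paths (eps=0.002, sigma=0.01, y0=-1,
    dt=1e-3) are stopped at y=-0.05; per run the inverse of the windowed
    fast-variable variance (window 50000, step 500) is fitted affinely
    over t in [0.05, 0.92] of the approach duration T=500 and the zero
    crossing compared with the true crossing.  The trend-model comparison
    runs on the run-averaged inverse variance.
    """
    eps = 0.002
    T = 1.0 / eps
    params = HopfParameters(
        epsilon=eps, sigma=0.01, y0=-1.0, x0=(0.1, 0.0), dt=1e-3,
        n_steps=int(0.95 * T / 1e-3),
    )
    paths = simulate_hopf_ensemble(params, n_runs, seed=seed)
    window_len, step = 50_000, 500
    preds = []
    inv_stack = []
    t_axis = None
    for p in paths:
        tr = sliding_variance(p.states[0], window_len, step)
        tsec = np.asarray(tr.window_centers) * p.dt
        idx = np.where((tsec >= 0.05 * T) & (tsec <= 0.92 * T))[0]
        rng = (int(idx[0]), int(idx[-1] + 1))
        fit = fit_inverse_variance_linear(tr, rng)
        preds.append(
            fit.predicted_transition * p.dt
            if fit.predicted_transition is not None
            else np.nan
        )
        inv_stack.append(1.0 / tr.values[rng[0] : rng[1]])
        t_axis = tsec[rng[0] : rng[1]]
    preds = np.asarray(preds)
    errors = np.abs(preds - T) / T
    comparison = compare_trend_models(t_axis, np.mean(inv_stack, axis=0))
    return HopfRecoveryResult(
        predictions=preds,
        true_transition=T,
        median_abs_error=float(np.nanmedian(errors)),
        model_rss=comparison["rss"],
        model_winner=comparison["winner"],
    )
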