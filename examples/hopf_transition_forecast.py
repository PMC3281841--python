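"""Forecasting a Hopf transition from the linear inverse-variance law.

Near a slowly driven Hopf bifurcation the variance of the fast variables
grows like 1/|y| where y is the drifting bifurcation parameter, so the
inverse variance decays as a straight line hitting zero exactly when y
crosses the bifurcation.  This script simulates a handful of driven
subcritical Hopf paths, fits that line per run and compares the
extrapolated transition time with the true crossing.
"""

import numpy as np

from seizuredyn import experiments

res = experiments.hopf_recovery_experiment(seed=0, n_runs=8)
print(f"true transition at t = {res.true_transition:.0f} time units")
for k, p in enumerate(res.predictions):
    print(f"  run {k}: predicted t = {p:7.1f}  "
          f"(error {100 * abs(p - res.true_transition) / res.true_transition:4.1f}%)")
print(f"median |error| = {100 * res.median_abs_error:.1f}% of the approach duration")
print(f"trend-model comparison on 1/Var: winner = {res.model_winner}")
print("\nThe zero crossing of the fitted 1/Var line lands close to the true")
print("bifurcation time: the linear scaling law turns windowed variance into")
print("a transition-time forecast.")
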