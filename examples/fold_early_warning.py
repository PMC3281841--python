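"""Variance growth as an early-warning sign of a fold-induced spike.

Runs a small ensemble of relaxation-regime FitzHugh-Nagumo paths sliding
down the left (refractory) branch toward the fold at x = -1, estimates
the sliding-window variance of the fast variable, and fits the pole law
Var(x) = D / (2 (x^2 - 1)).  A good fit (r^2 near 1) with a rising trend
means the variance announces the jump before it happens.
"""

from seizuredyn import experiments

res = experiments.fold_approach_experiment(seed=0, n_paths=40)
print(f"pole-law fit over {res.n_windows} windows:")
print(f"  r^2 = {res.r_squared:.3f}")
print(f"  fitted diffusion constant D = {res.diffusion_constant:.2e}")
print(f"  Spearman trend of the variance = {res.trend_rho:+.3f}")
print("\nr^2 near 1 and a strongly positive trend: the variance of the")
print("voltage variable diverges on the approach to the fold, so rising")
print("variance is a usable precursor of the spike.")
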