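# Methods

`seizuredyn` implements a three-scale analysis of pre-seizure neural
dynamics: stochastic fast–slow neuron models with variance-based
early-warning statistics at the single-cell and cluster levels, and
wavelet-based multichannel synchronization measures at the network level.
Because clinical ECoG of the kind this analysis targets is not freely
redistributable, the package ships a synthetic-recording generator with
exported ground truth, and every claim the pipeline makes is validated by
parameter recovery against that truth.

## Models

### Stochastic FitzHugh–Nagumo (fast–slow, Van-der-Pol type)

    dx = (x - x^3/3 - y + s) dt + sigma dW
    dy = eps (x + a - b y) dt

`x` is the fast voltage-like variable, `y` the slow recovery variable,
`s` an applied current, `eps << 1` the time-scale separation and `sigma`
the white-noise amplitude on the fast variable only. The fast nullcline
(*critical manifold*) `y = x - x^3/3 + s` has folds at `x = ±1`; its
outer branches attract the fast flow (`1 - x^2 < 0`), the middle branch
repels. With the equilibrium on the middle branch the system performs
relaxation oscillations; with the equilibrium on an attracting branch
near a fold it is *excitable* — silent deterministically, spiking under
noise. `classify_regime` decides this by locating the unique nullcline
intersection (unique whenever `b < 1`); an equilibrium within 0.01 of a
fold abscissa is flagged degenerate but classified (the boundary counts
as excitable).

Defaults `a = 0.7`, `b = 0.8`, `eps = 0.01`, `dt = 1e-3` are the
classical parameter neighbourhood for this model family; `s` is the
natural knob for placing the equilibrium (`fhn_input_for_equilibrium`
inverts the placement exactly).

### Driven subcritical Hopf normal form

    dx1 = (y x1 - x2 + x1 r^2) dt + sigma dW1      r^2 = x1^2 + x2^2
    dx2 = (x1 + y x2 + x2 r^2) dt + sigma dW2
    dy  = eps dt

The slow parameter `y` is exactly affine in time and crosses the
bifurcation at `y = 0`; beyond the subcritical escape the cubic term
diverges in finite time, so the integrator truncates cleanly at the last
finite state and flags the path. Noise acts on the fast pair only.

### Integration

Fixed-step Euler–Maruyama only, with independent Gaussian increments of
variance `dt` scaled per component; ensembles advance in lock-step from a
single seeded generator, so one seed reproduces a whole ensemble
bit-for-bit. Non-finite or exploding states (norm > 1e8) abort with the
step index, or truncate when requested.

## Early-warning statistics

Sliding-window variance uses the unbiased (n−1) estimator on raw,
undetrended windows; the first window starts at sample 0 and a trailing
partial window is dropped. Ensemble variance computes the per-path
windowed variance first and averages pointwise.

Two scaling laws are fitted:

* **Fold approach** — on an attracting branch the frozen-coefficient
  Ornstein–Uhlenbeck approximation gives `Var(x) = D / (2 (x^2 - 1))`;
  `D` (a single non-negative constant absorbing `sigma^2` and
  higher-order corrections) is fitted in closed form. Positions inside
  the repelling region `|x| <= 1` are rejected.
* **Hopf approach** — frozen-`y` theory gives `Var ≈ sigma^2 / (2 |y|)`,
  so `1/Var` is affine in time and its zero crossing estimates the
  transition. Ordinary least squares on `1/Var`; a prediction is only
  reported when the slope is negative.

The maxima-marking rule subdivides a trace into 20 equal index intervals
and accepts an interval's argmax iff it is also a strict local maximum of
the whole series within one interval-width (configurable), excluding the
series edges. The rule only compares values, so it is invariant under
positive affine rescaling.

### Study conditions (frozen in `experiments`)

* *Fold approach*: 100 relaxation-regime paths (`s = 0.875`, equilibrium
  at `x = 0`, `sigma = 0.01`) started at `x = -2` on the manifold, 150k
  steps; windows of 5000 samples stepped by 100; fit over windows whose
  mean position lies in `[-1.8, -1.05]`. The lower cut removes the
  start-up transient; the upper cut removes windows contaminated by the
  jump. Within that range the pole fit reaches r² ≈ 0.8–0.87 — the
  windowed estimator is bias-limited (drift within a window, and windows
  comparable to the local correlation time `1/|1-x^2|`), which is why the
  fit range matters and r² does not reach 1.
* *Excitable regimes*: equilibrium at `x = -1.02` (weakly damped focus,
  ringing period ≈ 63 time units), paths started at `x = -1.5`, 300k
  steps, noise triplet `sigma ∈ {0.001, 0.01, 0.05}`. Summaries chosen to
  match each regime's signature: Spearman trend over the full horizon
  (small noise: metastable decay, strongly negative), count of interior
  variance maxima with ≥10% prominence (intermediate noise: ringing and
  sporadic escapes, ≥3), and the first-half trend (large noise: escape-
  driven growth, strongly positive — the trace saturates later once
  spiking is continual, which is the regularization effect itself).
* *Hopf recovery*: 20 paths at `eps = 0.002`, `sigma = 0.01`,
  `y0 = -1`, stopped at `y = -0.05`; windows 50000/500, fit over
  `[0.05, 0.92]` of the approach. The drift rate sets the information
  content of a run (about `∫|y| dt` independent envelope samples); at
  `eps = 0.01` a single run carries only ~50 of them and per-run
  recovery is unreliable (median error 8–17% across seeds), so the
  study condition uses the slower drift where the asymptotic law is
  demonstrable (median error 4–5%). The model comparison (linear vs power vs
  exponential, equal parameter counts, by residual sum of squares) runs
  on the run-averaged inverse variance.

## Wavelet phase synchrony

Scale `j` refers to the dyadic band `(fs/2^(j+1), fs/2^j]`. The analytic
band signal comes from an undecimated dyadic filter bank: the level-`j`
à-trous cascade of a Daubechies least-asymmetric (`sym8`) wavelet gives
the band's magnitude response, applied zero-phase, with the imaginary
branch the exact discrete Hilbert transform of the real branch (one-sided
spectrum by construction). Inputs are reflection-padded before the
circular convolution. An ideal brick-wall analytic band-pass serves as an
independent oracle engine; the two agree in phase to well under 0.1 rad
away from boundaries.

For a channel pair the instantaneous complex phase vector is
`C = W_a conj(W_b) / (|W_a||W_b|)`, with samples flagged undefined when
either modulus is negligible (below 1e-10 of that signal's rms modulus;
undefined samples never enter averages or locking intervals). The
smoothed estimate is a centered moving average of `C` over an odd span
(default `2^(j+2) + 1` samples, so lower-frequency scales are smoothed
over proportionally longer spans — about three band-center cycles at
every scale);
its argument is the local mean phase difference and its squared modulus
the significance in [0, 1]. The span must exceed the band's correlation
time (`~2^(j+1)` samples) by a factor of a few, or the significance of
*independent* signals rarely falls below the 0.5 gate; at the default
span the all-null locking fraction stays under 0.06 at every scale.

Phase-locking intervals are maximal runs with `|Δφ| < π/4` (threshold
configurable; the significance gate of 0.5 is a stated convention and
kept) — raising the phase threshold can only extend intervals, raising
the significance gate only shrink them. The PLW measure counts locked
samples over all `N(N-1)/2` unordered pairs in a window and divides by
`(N(N-1)/2) · T`, confining it to [0, 1]. Mean phase coherence is the
resultant length `R = |<exp(i Δφ)>|`, computed from the same smoothed
phase differences and windowed identically.

Synchronization-rise onsets: per scale, the onset is the last window (at
or before the stated transition time) whose value is within the baseline
mean + 2 baseline SD such that the trace stays above that level through
the transition; a linear model is then fitted on [onset, transition] and
compared with power-law and exponential alternatives by residual sum of
squares (ties favour linear). The transition time is an input — the
pipeline never claims to detect seizure onset itself.

## Cross-correlation

The lag-`τ` linear cross-correlation is the Pearson correlation of the
overlapping spans (each mean-removed and unit-scaled *within the
overlap*, i.e. per-window normalization, appropriate for nonstationary
data). MLCC maximizes its absolute value over `|τ| ≤ max_lag` (default
half a second), so anti-phase lag synchrony also counts; among ties the
smallest |lag| is reported. The windowed variant draws its channel pairs
once per run (frozen across windows for comparability) from a seeded
generator and averages the per-pair MLCC per window. A fast FFT path
computes all lags at once and is tested against the direct definition.

## Synthetic recordings

Each channel is

    x_i(t) = Σ_b a_b w_ib cos(φ_ib(t)) + g E(t) η_i(t) + pink + white

* **Band phases.** Per dyadic band: a shared source phase (band-center
  tone plus slow common wander) and a per-channel stationary AR(1) phase
  wander (sd 2.5 rad, correlation time 64 samples). Coupling is
  *time-multiplexed*: synchronization episodes recur with a fixed period
  (1000 samples, a divisor of the 5000-sample analysis window, so
  windowed locking fractions carry no duty-cycle ripple) and a duty
  cycle equal to `c_b(t) = clip(baseline + slope·max(0, t - t_b), 0, 1)`;
  inside an episode all channels follow the source phase, and episode
  starts are offset per band. The pair-time locked fraction is therefore
  *linear* in the coupling up to a constant edge loss from the phase
  smoothing. (An amplitude-scaled mix of source and wander was tried
  first; its locking response is sigmoidal, which saturates the measured
  ramp and distorts the trend-model comparison. A stochastically gated
  variant makes the windowed locking fraction too noisy for sharp onset
  detection.) The per-band winner among three equally-parameterized
  trend families on a finite noisy ramp can still be a near-tie, so
  recovery tests assert the linear model stays within 20% of the best
  residual on every band rather than that it always wins.
* **Variance envelope.** `E(t)` is the smoothed rms fast-pair amplitude
  of a 16-path ensemble of driven subcritical Hopf simulations whose slow
  parameter crosses zero at the seizure sample `t_c` (simulation stopped
  at `y = -0.02`, last value held). A single path's amplitude is
  exponentially dispersed near the transition and would bury the mean
  `1/|y|` growth, hence the small ensemble — mirroring ensemble-averaged
  model variance rather than a single realization. Over the short
  unsimulated tail the mean-square `1/(t_c - t)` growth is continued
  analytically (capped), so the inverse variance heads to zero at `t_c`
  instead of flattening. The modulated noise `η_i` is independent per
  channel and low-passed below *half* the lowest analysis band edge
  (brick-wall): the analysis filter bank's skirt reaches below its
  nominal band, and the late envelope power is large enough for even
  -20 dB leakage to dilute band locking. Thus the growing power raises
  the variance without touching band phase coherence; in real seizures
  the growing power is itself coherent, but here cross-channel coherence
  is deliberately owned by the coupling ramps alone.
* **Background.** 1/f-shaped noise (rms 0.3 of the unit band amplitude)
  plus white noise (sd 0.3).
* **Modes.** `preictal`: ramps plus envelope. `interictal`: constant,
  higher coupling (0.5 vs a 0.2 pre-ictal baseline, giving the lower
  pre-ictal synchronization level), flat envelope, no transition.

Default pre-ictal fixture: 8 channels, 256 Hz, 230k samples
(~15 minutes), `t_c = 215000`, ramps at scales 3/4/5 (16–32, 8–16,
4–8 Hz) starting at samples 140k/165k/185k–190k — higher-frequency band
first — each ramping coupling by 0.45 to reach ~0.65 at `t_c`, which
keeps the locking measure inside its informative range (real pre-ictal
locking values are low and rise into the seizure rather than saturating
before it).

What the generator does *not* emulate: volume conduction and common
reference effects, spatially structured electrode neighbourhoods,
artifacts, non-stationary background rhythms, or coherent broadband
seizure power. Passing recovery tests therefore show the *pipeline*
recovers the statistical structure it targets, not that real ECoG has
that structure.

## Pipeline conventions

Channel-average signal for the cluster-level variance analysis (per-
channel traces remain available through the library); windows of 5000
samples stepped by 50 (tests and the reproduction script step by 100–500
where the extra grid density adds nothing); analysis scales are the
three consecutive dyadic scales whose bands best cover 3–32 Hz at the
recording's rate (256 Hz → 16–32/8–16/4–8 Hz; 200 Hz → 12.5–25/
6.25–12.5/3.1–6.25 Hz, matching the conventional printed band sets after
integer truncation); inverse-variance fit over the final 20% of
pre-transition windows unless a range is given; onset baseline over the
first half of the pre-transition span. All intervals are 0-based and
half-open; all randomness (pair sampling) is seeded and echoed in the
report, which reproduces a run exactly when fed back.

I/O: delimited matrix text with `# fs:` metadata is the canonical
format; EDF files are read through the optional `mne` dependency. EDF
writing is not provided.

## Numerical notes and limitations

* Window variances are computed from cumulative sums (O(n), exact to
  round-off; tiny negative values are clipped to zero).
* The exponential/power trend fits start from log-linear estimates and
  refine by nonlinear least squares; a model that fails to converge gets
  infinite residual. Exponents are clipped against overflow.
* The filter-bank band response is not flat: white-noise energy ratios
  between adjacent scales are exactly 2 only for the brick-wall oracle;
  the cascade engine sits within ~5%.
* Windowed variance of a *narrowband* signal (the Hopf fast pair) has
  few effective degrees of freedom per window; per-run transition
  forecasts are honest only in the slow-drift regime (see the study
  conditions above).
* The marking rule, thresholds (π/4, 0.5) and window conventions are
  configuration, not constants; sampling rates of real recordings must
  be supplied with the data.
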