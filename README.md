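# seizuredyn

Multiscale early-warning and synchronization analysis of pre-ictal
neural recordings.

Epileptic seizures are abrupt transitions into hypersynchronous brain
activity. Dynamical-systems theory predicts that such *critical
transitions* cast statistical shadows ahead of themselves — and that the
shadow looks different at each spatial scale of the system:

* **Single neurons.** In a stochastic FitzHugh–Nagumo model
  (`dx = (x - x³/3 - y + s) dt + σ dW`, `dy = ε (x + a - by) dt`), the
  variance of the fast voltage variable diverges on the approach to a
  fold of the critical manifold as `Var(x) = D / (2(x² - 1))`, so rising
  variance is an early-warning sign of a spike. Whether it is *usable*
  depends on the noise level: in the excitable regime the ensemble
  variance decreases (tiny noise, metastable trapping), oscillates
  (intermediate noise, ringing of the near-fold focus), or grows
  (larger noise, escape-driven regularization).
* **Neuronal clusters.** Near a slowly driven (sub)critical Hopf
  bifurcation — the transition mechanism many mean-field seizure models
  share — the variance grows like `σ²/(2|y|)` with `y` the drifting
  bifurcation parameter, so the **inverse** variance decays as a straight
  line whose zero crossing forecasts the transition time.
* **Brain regions.** Pairwise synchrony measured per dyadic frequency
  band `(fs/2^(j+1), fs/2^j]` via Hilbert-wavelet phase-locking
  intervals: the PLW measure (fraction of pair-time locked, in [0, 1]),
  mean phase coherence `R = |⟨e^{iΔφ}⟩|`, and maximum linear
  cross-correlation (MLCC) over lags. Pre-ictally the synchrony baseline
  sits *below* the inter-ictal level, then rises roughly linearly toward
  the seizure — starting at different times in different bands.

Clinical ECoG of the kind this analysis targets is not freely
redistributable, so the package ships a synthetic multichannel generator
that produces recordings with exactly this statistical structure plus
the hidden ground truth (seizure time, band coupling onsets and slopes).
Every pipeline stage is validated by recovering that truth. See
`docs/methods.md` for the models, estimators, and design choices.

## Worked example

`examples/full_preictal_analysis.py` generates the default 8-channel
pre-ictal recording (256 Hz, 230 000 samples, seizure at sample 215 000,
band coupling ramps starting at samples 140 000 / 165 000 / 190 000) and
runs the complete analysis:

```
recording: 8 channels x 230000 samples at 256 Hz; true seizure time t_c = 215000

inverse-variance fit: slope = -1.908e-05
predicted transition = 220775 (2.7% from truth)
marked variance maxima: 7
scale 3: detected synchronization onset 143500 (true 140000; best trend: linear)
scale 4: detected synchronization onset 164500 (true 165000; best trend: linear)
scale 5: detected synchronization onset 189500 (true 190000; best trend: linear)
```

Reading the numbers: the inverse variance of the channel-average signal
decays linearly and its extrapolated zero crossing lands under 3% from
the true seizure time; on the way it oscillates (7 marked local maxima, the
interval-subdivision marking rule); and the per-band phase-locking rise
is detected close to each band's true coupling onset, in the correct
temporal order (16–32 Hz first), with a linear trend beating power-law
and exponential fits.

The other scripts in `examples/` each demonstrate one capability:
neuron-regime simulation, the fold pole-law fit, the Hopf
transition forecast, and the three synchrony measures on controlled
inputs.

A thin CLI wraps the same machinery:

```
seizuredyn simulate --model preictal_default --seed 1 --out rec.tsv
seizuredyn analyze rec.tsv --out report.json --transition-time 215000
seizuredyn report report.json
```

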