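"""The three pairwise synchrony measures on controlled inputs.

Computes MLCC (lag cross-correlation), PLW (wavelet phase-locking
fraction) and MPC (mean phase coherence) on signals whose answers are
known: identical channels, a lagged copy, and independent noise.
"""

import numpy as np

from seizuredyn import crosscorr as cc
from seizuredyn import wavelet_phase as wp

fs = 256.0
rng = np.random.default_rng(0)
x = rng.standard_normal(12_000)
lagged = np.roll(x, 37)
independent = rng.standard_normal(12_000)

r = cc.mlcc(x, lagged, max_lag=100)
print(f"MLCC of a 37-sample lagged copy : {r.value:.3f} at lag {r.lag}")
print(f"MLCC of independent noise      : {cc.mlcc(x, independent, 100).value:.3f}")

signals = np.stack([x, x, independent])
plw = wp.plw_measure(signals, fs, scale_j=3, window_len=2000, step=1000)
print(f"PLW (2 identical + 1 independent channel), 16-32 Hz band: "
      f"mean {plw.values.mean():.3f}")

bands = wp.hilbert_wavelet_transform(x, fs, [3])
c = wp.complex_phase_vector(bands[0], bands[0])
p = wp.smoothed_phase_difference(c, 9)
print(f"MPC of a channel with itself   : {wp.mean_phase_coherence(p.phase_diff):.3f}")

print("\nIdentical channels give 1 (and the imposed lag is recovered exactly);")
print("independent channels give values near 0, so each measure separates")
print("true coupling from chance alignment.")
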