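"""Six-parameter spectral fit: P(f) = b + S·f^-k + A·exp(-(f-c)²/2w²).

Round-trips a noiseless model spectrum through the bounded least-squares
fit, then fits a realistic noisy Welch estimate, printing recovered vs true
parameters and the goodness of fit R².
"""

import numpy as np

import qeeglda as q
from qeeglda.montage import FREQ_GRID, PARAM_NAMES

true = np.array([20.0, 1.5, 5.0, 10.0, 1.5, 1.0])  # S, k, A, c, w, b
clean = q.model_curve(true, FREQ_GRID)
fit = q.fit_spectrum(FREQ_GRID, clean)
print("noiseless round trip (true -> fitted):")
for name, t, f in zip(PARAM_NAMES, true, fit.as_array()):
    print(f"  {name}: {t:8.3f} -> {f:8.5f}")
print(f"  R² = {fit.r2:.6f}\n")

profile = q.make_group_profile("AD", effect_scale=1.0)
truth = q.sample_subject(profile, seed=3)
noisy = q.synthesize_spectra(truth, n_epochs=334, seed=4)
ch = q.CHANNELS.index("Pz")
fit_n = q.fit_spectrum(noisy.freqs, noisy.power[ch])
print(f"noisy fit at Pz (334-epoch Welch noise), R² = {fit_n.r2:.3f}:")
for name, t, f in zip(PARAM_NAMES, truth.params[ch], fit_n.as_array()):
    print(f"  {name}: true {t:7.3f}   fitted {f:7.3f}")
print("\nReading: with the protocol's ~5.5 min of clean data per channel, "
      "the alpha center lands within a fraction of a 0.5-Hz bin; k and b "
      "trade off against each other (both set the high-frequency floor), "
      "which is why their fitted values co-vary.")
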