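"""From raw multi-channel time series to per-channel average spectra.

Synthesizes one subject's 22-channel recording (with a couple of injected
high-amplitude artifacts), runs the clinical pre-processing chain —
resampling, zero-phase 0.5-50 Hz FIR band-pass, 1-s artifact rejection,
2-s/1-s-overlap Welch epoching, FFT — and reports what survived.
"""

import numpy as np

import qeeglda as q
from qeeglda.spectra import compute_subject_spectra

profile = q.make_group_profile("HC", effect_scale=1.0)
truth = q.sample_subject(profile, seed=7, subject_id="demo")
signal = q.synthesize_timeseries(truth, duration_s=370.0, fs=256.0,
                                 artifact_rate=0.01, seed=8)
print(f"raw signal: {signal.n_samples} samples × 22 channels at {signal.fs} Hz "
      f"({signal.duration_s:.0f} s), {len(signal.artifact_times)} artifacts injected")

spectra, quality = compute_subject_spectra(signal, subject_id="demo",
                                           truncate_to=334)
print(f"1-s epochs rejected: {int(quality.rejected.sum())} "
      f"(amplitude > {quality.thresholds['amplitude_uv']:.0f} µV, "
      f"power z > {quality.thresholds['power_z']:.0f}, "
      f"sSTD z > {quality.thresholds['sstd_z']:.0f})")
print(f"averaged {spectra.n_epochs} two-second epochs -> "
      f"{spectra.power.shape[0]} channels × {spectra.power.shape[1]} bins")

o1 = q.CHANNELS.index("O1")
alpha = (spectra.freqs >= 8) & (spectra.freqs <= 13)
peak = spectra.freqs[alpha][np.argmax(spectra.power[o1][alpha])]
print(f"\nO1 alpha peak in the estimate: {peak:.1f} Hz "
      f"(true center {truth.params[o1, 3]:.1f} Hz)")
print("Reading: the Welch average reproduces the subject's true spectral "
      "shape; injected artifacts were caught by the 1-s screening.")
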