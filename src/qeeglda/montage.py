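"""Standard 10-20 montage and parameter naming shared across the package.

The recording layout is a 22-channel clinical montage (10-20 placements
including both mastoids). Posterior channels are the temporo-parieto-occipital
subset where the alpha rhythm dominates and where dementia-related alpha
changes are expected.
"""

from __future__ import annotations

import numpy as np

#: 22-channel clinical 10-20 montage (T3/T4, T5/T6 are the older names for
#: T7/T8, P7/P8; M1/M2 are the mastoids, treated as analysis channels).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
    "M1", "M2",
)

N_CHANNELS = len(CHANNELS)

#: Posterior channels carrying the dominant alpha rhythm.
POSTERIOR_CHANNELS: tuple[str, ...] = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")

#: The six spectral parameters, in canonical order: delta power scale S,
#: 1/f decay exponent k, alpha amplitude A, alpha center c, alpha width w,
#: baseline offset b.
PARAM_NAMES: tuple[str, ...] = ("S", "k", "A", "c", "w", "b")

N_PARAMS = len(PARAM_NAMES)

#: Analysis frequency grid: 100 bins, 0.5 Hz steps from 0.5 to 50 Hz.
FREQ_GRID: np.ndarray = np.round(np.arange(1, 101) * 0.5, 6)

POSTERIOR_IDX = np.array([CHANNELS.index(ch) for ch in POSTERIOR_CHANNELS])
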