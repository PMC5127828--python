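"""Plain-text I/O for signals, spectra and fit tables; optional EDF input."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MultiChannelSignal
from .montage import CHANNELS, FREQ_GRID
from .spectra import SubjectSpectra


def write_signal_csv(sig: MultiChannelSignal, path) -> None:
    """Time × channels CSV with a header row naming channels; fs in a comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={sig.fs}\n")
        pd.DataFrame(sig.data, columns=list(sig.channels)).to_csv(fh, index=False)


def read_signal_csv(path) -> MultiChannelSignal:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        fs = float(header.split("=", 1)[1]) if header.startswith("# fs_hz=") else 256.0
        df = pd.read_csv(fh)
    return MultiChannelSignal(df[list(CHANNELS)].to_numpy(float), fs)


def spectra_to_frame(spectra: list[SubjectSpectra]) -> pd.DataFrame:
    """Long table: subject, channel, frequency_hz, power_uv2, n_epochs."""
    rows = []
    for ss in spectra:
        for ci, ch in enumerate(CHANNELS):
            rows.append(pd.DataFrame({
                "subject": ss.subject_id, "channel": ch,
                "frequency_hz": ss.freqs, "power_uv2": ss.power[ci],
                "n_epochs": ss.n_epochs,
            }))
    return pd.concat(rows, ignore_index=True)


def frame_to_spectra(df: pd.DataFrame) -> list[SubjectSpectra]:
    out = []
    for sid, sub in df.groupby("subject", sort=False):
        power = np.zeros((len(CHANNELS), FREQ_GRID.size))
        for ci, ch in enumerate(CHANNELS):
            chd = sub[sub["channel"] == ch].sort_values("frequency_hz")
            if len(chd) != FREQ_GRID.size:
                raise ValueError(f"subject {sid!r} channel {ch!r}: incomplete spectrum")
            power[ci] = chd["power_uv2"].to_numpy()
        out.append(SubjectSpectra(FREQ_GRID.copy(), power, int(sub["n_epochs"].iloc[0]), str(sid)))
    return out


def load_edf(path, fs_fallback: float = 256.0) -> MultiChannelSignal:
    """Read a 10-20 EDF recording into the 22-channel montage (needs mne).

    Channel names are matched case-insensitively, accepting the older
    T3/T4/T5/T6 or newer T7/T8/P7/P8 temporal labels and ignoring reference
    suffixes like "EEG Fp1-REF".
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    alt = {"T3": ("T3", "T7"), "T4": ("T4", "T8"), "T5": ("T5", "P7"), "T6": ("T6", "P8")}
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")

    def norm(name: str) -> str:
        n = name.upper().replace("EEG", "").strip()
        return n.split("-")[0].strip()

    available = {norm(n): n for n in raw.ch_names}
    picks = []
    for ch in CHANNELS:
        cands = alt.get(ch, (ch,))
        hit = next((available[c.upper()] for c in cands if c.upper() in available), None)
        if hit is None:
            raise ValueError(f"EDF file lacks channel {ch!r}")
        picks.append(hit)
    data = raw.get_data(picks=picks).T * 1e6  # volts -> µV
    return MultiChannelSignal(data, float(raw.info["sfreq"] or fs_fallback))
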