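"""Time series → per-channel average power spectra.

Implements the clinical-qEEG preprocessing chain: polyphase resampling to
256 Hz, zero-phase least-squares FIR band-pass 0.5-50 Hz (order 1536),
1-s artifact-rejection epochs (amplitude / power-z / spatial-STD-z
thresholds), re-segmentation into 2-s epochs with 1-s overlap (equivalent to
Welch's method with a rectangular window and 50% overlap), rectangular-window
FFT power on the 0.5-50 Hz / 0.5-Hz grid (100 bins per channel), and
arithmetic averaging over epochs.

Power convention: each bin holds total power per 0.5-Hz bin, normalized so
that the sum over all non-DC FFT bins equals the epoch's time-domain
variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cohort import MultiChannelSignal, VALID_FS
from .montage import FREQ_GRID, N_CHANNELS

TARGET_FS = 256.0
HP_ORDER = 1536  # taps = order + 1, type-I linear phase


@dataclass
class EpochSet:
    """Epoch tensor (epochs × samples × channels, µV) with segmentation info."""

    data: np.ndarray
    length_s: float
    overlap_s: float
    fs: float
    keep: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("epoch tensor must be (epochs, samples, channels)")
        if abs(self.length_s * self.fs - self.data.shape[1]) > 1e-9:
            raise ValueError("epoch length × fs must equal the sample count")
        if self.overlap_s >= self.length_s:
            raise ValueError("overlap must be shorter than the epoch length")
        if self.keep is None:
            self.keep = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochQuality:
    """Per-1-s-epoch artifact metrics and the rejection decision."""

    max_amplitude: np.ndarray      # µV, max |x| over samples and channels
    power: np.ndarray              # µV², mean square over samples and channels
    power_z: np.ndarray
    sstd: np.ndarray               # spatial STD of per-channel log10 power
    sstd_z: np.ndarray
    rejected: np.ndarray           # bool mask
    thresholds: dict


@dataclass
class SubjectSpectra:
    """Per-channel average power spectra on the 100-bin 0.5-50 Hz grid."""

    freqs: np.ndarray              # (100,) Hz
    power: np.ndarray              # (22, 100) µV² per 0.5-Hz bin
    n_epochs: int
    subject_id: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != (100,) or not np.allclose(self.freqs, FREQ_GRID):
            raise ValueError("frequency grid must be 0.5:0.5:50 Hz (100 bins)")
        if self.power.shape != (N_CHANNELS, 100):
            raise ValueError("power must be (22 channels, 100 bins)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def resample_to_256(sig: MultiChannelSignal) -> MultiChannelSignal:
    """Band-limited polyphase resampling to 256 Hz (no-op at 256 Hz)."""
    if float(sig.fs) not in VALID_FS:
        raise ValueError(f"unsupported sampling rate {sig.fs}; expected one of {VALID_FS}")
    if sig.fs == TARGET_FS:
        return sig
    from fractions import Fraction

    frac = Fraction(int(TARGET_FS), int(sig.fs))
    data = sps.resample_poly(sig.data, frac.numerator, frac.denominator, axis=0)
    return MultiChannelSignal(data, TARGET_FS, artifact_times=sig.artifact_times)


def design_bandpass(fs: float = TARGET_FS, lo: float = 0.5, hi: float = 50.0,
                    order: int = HP_ORDER, lp_order: int = 256) -> np.ndarray:
    """Least-squares linear-phase FIR band-pass as a high-pass/low-pass cascade.

    A 1536-order least-squares high-pass with cut-off ``lo`` (transition from
    ``lo`` − 0.25 Hz) is convolved with a shorter least-squares low-pass with
    cut-off ``hi`` (transition to ``hi`` + 2 Hz). Designing the two halves
    separately keeps the least-squares system well conditioned; the combined
    kernel remains symmetric (linear phase).
    """
    nyq = fs / 2.0
    lo_t = max(lo - 0.25, 0.05)
    hi_t = min(hi + 2.0, nyq - 0.5)
    hp = sps.firls(order + 1, [0.0, lo_t, lo, nyq], [0.0, 0.0, 1.0, 1.0], fs=fs)
    lp = sps.firls(lp_order + 1, [0.0, hi, hi_t, nyq], [1.0, 1.0, 0.0, 0.0], fs=fs)
    return np.convolve(hp, lp)


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR forward and time-reversed (zero phase) via FFT.

    Equivalent to filtfilt for a linear-phase FIR, but uses overlap-add FFT
    convolution, which is vastly faster at ~10^3 taps on minutes of data.
    Edges are reflect-padded by the filter length.
    """
    n_taps = taps.size
    pad = n_taps
    padded = np.concatenate([data[pad:0:-1], data, data[-2:-pad - 2:-1]], axis=0)
    once = sps.oaconvolve(padded, taps[:, None], mode="same", axes=0)
    twice = sps.oaconvolve(once, taps[::-1][:, None], mode="same", axes=0)
    return twice[pad:pad + data.shape[0]]


def bandpass_filter(sig: MultiChannelSignal, lo: float = 0.5, hi: float = 50.0) -> MultiChannelSignal:
    """Zero-phase 0.5-50 Hz band-pass at 256 Hz (1536-order least-squares FIR)."""
    if sig.fs != TARGET_FS:
        raise ValueError("bandpass_filter expects data already resampled to 256 Hz")
    taps = design_bandpass(sig.fs, lo, hi)
    if sig.n_samples < taps.size + 2:
        raise ValueError("signal shorter than the filter")
    data = _zero_phase_fir(sig.data, taps)
    return MultiChannelSignal(data, sig.fs, artifact_times=sig.artifact_times)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def reject_artifact_epochs(
    sig: MultiChannelSignal,
    amplitude_uv: float = 100.0,
    power_z_max: float = 4.0,
    sstd_z_max: float = 3.0,
) -> tuple[MultiChannelSignal, EpochQuality]:
    """Drop contaminated 1-s epochs and re-concatenate the survivors.

    An epoch is rejected when any criterion fires: max |amplitude| above
    ``amplitude_uv``; broadband power z-score (across epochs) above
    ``power_z_max``; spatial-STD (sSTD) z-score above ``sstd_z_max``. The
    sSTD index of an epoch is the standard deviation across the 22 channels
    of per-channel log10 broadband power, z-scored across epochs.
    """
    fs = sig.fs
    n_len = int(round(fs))
    n_ep = sig.n_samples // n_len
    if n_ep == 0:
        raise ValueError("signal shorter than one rejection epoch")
    x = sig.data[: n_ep * n_len].reshape(n_ep, n_len, -1)

    max_amp = np.abs(x).max(axis=(1, 2))
    chan_power = np.mean(x**2, axis=1)            # (n_ep, 22)
    power = chan_power.mean(axis=1)
    power_z = _zscore(power)
    sstd = np.log10(chan_power + 1e-12).std(axis=1)
    sstd_z = _zscore(sstd)

    rejected = (max_amp > amplitude_uv) | (power_z > power_z_max) | (sstd_z > sstd_z_max)
    if rejected.all():
        raise ValueError("all epochs rejected; thresholds too strict for this record")
    quality = EpochQuality(
        max_amplitude=max_amp, power=power, power_z=power_z,
        sstd=sstd, sstd_z=sstd_z, rejected=rejected,
        thresholds={"amplitude_uv": amplitude_uv, "power_z": power_z_max, "sstd_z": sstd_z_max},
    )
    clean = x[~rejected].reshape(-1, sig.data.shape[1])
    return MultiChannelSignal(clean, fs), quality


def segment_epochs(sig: MultiChannelSignal, length_s: float = 2.0, overlap_s: float = 1.0) -> EpochSet:
    """Segment into overlapping epochs covering the signal left to right.

    Epoch count = floor((duration - length) / (length - overlap)) + 1; a
    335-s record yields 334 two-second epochs at 1-s overlap.
    """
    n_len = int(round(length_s * sig.fs))
    step = int(round((length_s - overlap_s) * sig.fs))
    if step <= 0:
        raise ValueError("overlap must be shorter than the epoch length")
    if sig.n_samples < n_len:
        raise ValueError("signal shorter than one epoch")
    n_ep = (sig.n_samples - n_len) // step + 1
    idx = np.arange(n_len)[None, :] + step * np.arange(n_ep)[:, None]
    return EpochSet(sig.data[idx], length_s, overlap_s, sig.fs)


def epoch_spectrum(epochs, fs: float = TARGET_FS, full_band: bool = False):
    """Rectangular-window FFT power of 2-s epochs on the 0.5-Hz grid.

    Accepts an :class:`EpochSet` or an array shaped (samples, channels) or
    (epochs, samples, channels); epochs must hold 2 s × ``fs`` samples.
    Returns power shaped (..., channels, bins). One-sided powers are scaled
    so the sum over all non-DC bins equals the epoch's time-domain variance;
    by default only the 100 bins at 0.5-50 Hz are returned
    (``full_band=True`` returns every bin up to Nyquist plus its grid).
    """
    if isinstance(epochs, EpochSet):
        if epochs.fs != fs:
            raise ValueError("EpochSet sampling rate disagrees with fs")
        data = epochs.data
    else:
        data = np.asarray(epochs, float)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    n = data.shape[1]
    if n != int(round(2.0 * fs)):
        raise ValueError(f"epochs must hold exactly {int(2 * fs)} samples (2 s at {fs} Hz)")
    spec = np.fft.rfft(data, axis=1)
    power = (np.abs(spec) ** 2) / n**2
    power[:, 1:-1] *= 2.0  # one-sided doubling (DC and Nyquist excluded)
    power = np.moveaxis(power, 1, 2)  # (epochs, channels, bins)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if not full_band:
        sel = (freqs >= FREQ_GRID[0] - 1e-9) & (freqs <= FREQ_GRID[-1] + 1e-9)
        power = power[:, :, sel]
        freqs = freqs[sel]
    if squeeze:
        power = power[0]
    return (power, freqs) if full_band else power


def average_spectrum(epoch_powers: np.ndarray, truncate_to: int | None = None,
                     subject_id: str = "") -> SubjectSpectra:
    """Average per-epoch spectra (epochs × 22 × 100) into one SubjectSpectra.

    ``truncate_to`` keeps only the first N epochs, standardizing the amount
    of data entering each subject's average.
    """
    powers = np.asarray(epoch_powers, float)
    if powers.ndim != 3 or powers.shape[0] < 1:
        raise ValueError("need a non-empty (epochs, channels, bins) array")
    if truncate_to is not None:
        if truncate_to > powers.shape[0]:
            raise ValueError(
                f"truncate_to={truncate_to} exceeds the {powers.shape[0]} available epochs"
            )
        powers = powers[:truncate_to]
    return SubjectSpectra(
        freqs=FREQ_GRID.copy(), power=powers.mean(axis=0),
        n_epochs=powers.shape[0], subject_id=subject_id,
    )


def compute_subject_spectra(
    sig: MultiChannelSignal,
    subject_id: str = "",
    truncate_to: int | None = 334,
    amplitude_uv: float = 100.0,
    power_z_max: float = 4.0,
    sstd_z_max: float = 3.0,
    bandpass: bool = True,
) -> tuple[SubjectSpectra, EpochQuality]:
    """Full chain: resample → band-pass → reject → segment → FFT → average.

    If fewer than ``truncate_to`` clean 2-s epochs survive, all survivors are
    averaged (the count is recorded on the result).
    """
    sig = resample_to_256(sig)
    if bandpass:
        sig = bandpass_filter(sig)
    clean, quality = reject_artifact_epochs(
        sig, amplitude_uv=amplitude_uv, power_z_max=power_z_max, sstd_z_max=sstd_z_max
    )
    epochs = segment_epochs(clean, 2.0, 1.0)
    powers = epoch_spectrum(epochs)
    n_avail = powers.shape[0]
    n_use = min(truncate_to, n_avail) if truncate_to is not None else n_avail
    spectra = average_spectrum(powers, truncate_to=n_use, subject_id=subject_id)
    return spectra, quality
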