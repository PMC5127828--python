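"""Synthetic resting-EEG cohort generator for HC / AD-like / VaD-like groups.

The clinical recordings behind the original study are not publicly
deposited, so evaluation runs on synthetic cohorts whose ground truth lives
in the same six-parameter space the estimation pipeline fits. Group profiles
encode the qualitative spectral contrasts reported for dementia:

* AD-like: reduced posterior alpha amplitude, slowed posterior alpha center,
  globally increased delta power.
* VaD-like: stronger global delta increase than AD, globally reduced alpha
  amplitude, and the same posterior alpha slowing (reduced posterior dominant
  rhythm frequency is described for both dementias).

All deviations from the healthy-control base scale linearly with
``effect_scale``; at 0 the three groups are identical (the null cohort used
for chance-level calibration). Subjects are drawn with a subject-level
parameter deviation shared across channels plus a smaller independent
per-channel deviation, both normal and clipped at the parameter bounds.

Time series are built by random-phase inverse-FFT colored noise whose
expected power spectrum equals the model curve of :mod:`qeeglda.specfit`,
optionally contaminated with high-amplitude transient artifacts. A direct
spectra mode bypasses time-series synthesis (Welch-estimate noise is modeled
as per-bin Gamma multiplicative noise) for fast cohort-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import (
    CHANNELS,
    FREQ_GRID,
    N_CHANNELS,
    N_PARAMS,
    PARAM_NAMES,
    POSTERIOR_IDX,
)
from .specfit import model_curve

GROUPS = ("HC", "AD", "VaD")

#: Parameter bounds used when clipping subject draws: (low, high) per parameter.
PARAM_CLIP_LOW = np.array([0.0, 0.0, 0.0, 6.0, 0.3, 0.0])
PARAM_CLIP_HIGH = np.array([np.inf, 5.0, np.inf, 14.0, 5.0, np.inf])

#: Healthy-control base profile: anterior/posterior alpha asymmetry, small
#: broadband baseline. S, A, b in µV² per 0.5-Hz bin; c, w in Hz. The scale
#: puts typical per-channel signal SD near 12-15 µV, a realistic resting-EEG
#: amplitude comfortably below clinical artifact thresholds.
BASE_S = 10.0
BASE_K = 1.5
BASE_A_ANTERIOR = 4.0
BASE_A_POSTERIOR = 9.0
BASE_C = 10.0
BASE_W = 1.5
BASE_B = 0.5

#: Between-subject jitter SDs per parameter (S, k, A, c, w, b): a deviation
#: shared across all channels of a subject, plus a smaller independent
#: per-channel deviation.
DEFAULT_JITTER_SUBJECT = np.array([5.0, 0.4, 2.5, 1.0, 0.3, 0.25])
DEFAULT_JITTER_CHANNEL = np.array([2.0, 0.15, 1.2, 0.4, 0.15, 0.08])

# Group effect sizes at effect_scale = 1 (multiplicative factors, additive Hz
# shift for the alpha center).
AD_S_FACTOR = 1.3          # global delta increase
AD_A_POST_FACTOR = 0.7     # posterior alpha reduction
AD_C_POST_SHIFT = -1.0     # posterior alpha slowing, Hz
VAD_S_FACTOR = 1.8         # stronger global delta increase
VAD_A_FACTOR = 0.8         # global alpha reduction
VAD_C_POST_SHIFT = -1.0    # posterior alpha slowing shared with AD, Hz

VALID_FS = (128.0, 256.0, 500.0)


def _base_param_matrix() -> np.ndarray:
    params = np.zeros((N_CHANNELS, N_PARAMS))
    params[:, 0] = BASE_S
    params[:, 1] = BASE_K
    params[:, 2] = BASE_A_ANTERIOR
    params[POSTERIOR_IDX, 2] = BASE_A_POSTERIOR
    params[:, 3] = BASE_C
    params[:, 4] = BASE_W
    params[:, 5] = BASE_B
    return params


@dataclass
class GroundTruthProfile:
    """Group-level true spectral parameters for all 22 channels."""

    group_label: str
    params: np.ndarray  # (22, 6) in PARAM_NAMES order
    jitter_subject: np.ndarray = field(
        default_factory=lambda: DEFAULT_JITTER_SUBJECT.copy()
    )
    jitter_channel: np.ndarray = field(
        default_factory=lambda: DEFAULT_JITTER_CHANNEL.copy()
    )
    effect_scale: float = 1.0

    def __post_init__(self):
        self.params = np.asarray(self.params, float)
        if self.params.shape != (N_CHANNELS, N_PARAMS):
            raise ValueError("profile params must be (22, 6)")
        for jit in (self.jitter_subject, self.jitter_channel):
            jit = np.asarray(jit, float)
            if not np.all(np.isfinite(jit)) or np.any(jit < 0):
                raise ValueError("jitter scales must be finite and non-negative")
        if np.any(self.params < PARAM_CLIP_LOW) or np.any(
            self.params > PARAM_CLIP_HIGH
        ):
            raise ValueError("profile parameters violate bounds")


@dataclass
class SubjectTruth:
    """Realized per-channel parameters for one simulated subject."""

    subject_id: str
    group_label: str
    params: np.ndarray  # (22, 6)
    seed: int

    def param_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(PARAM_NAMES))
        df.insert(0, "channel", list(CHANNELS))
        df.insert(0, "subject", self.subject_id)
        return df


@dataclass
class MultiChannelSignal:
    """A 22-channel EEG segment: samples (time × channels, µV) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = CHANNELS
    artifact_times: tuple[float, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise ValueError("signal must be (n_samples, n_channels)")
        if tuple(self.channels) != CHANNELS:
            raise ValueError("channel labels must match the 22-channel montage")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs


def make_group_profile(
    group_label: str,
    effect_scale: float = 1.0,
    base_params: np.ndarray | None = None,
    jitter_subject=None,
    jitter_channel=None,
) -> GroundTruthProfile:
    """Build the ground-truth profile for one diagnostic group.

    HC is the base profile; AD and VaD deviate in the directions described
    for dementia spectra, linearly in ``effect_scale``.
    """
    if group_label not in GROUPS:
        raise ValueError(f"unknown group label {group_label!r}; expected one of {GROUPS}")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    e = float(effect_scale)
    params = (_base_param_matrix() if base_params is None else np.array(base_params, float)).copy()

    def scaled(factor):
        return 1.0 + e * (factor - 1.0)

    if group_label == "AD":
        params[:, 0] *= scaled(AD_S_FACTOR)
        params[POSTERIOR_IDX, 2] *= scaled(AD_A_POST_FACTOR)
        params[POSTERIOR_IDX, 3] += e * AD_C_POST_SHIFT
    elif group_label == "VaD":
        params[:, 0] *= scaled(VAD_S_FACTOR)
        params[:, 2] *= scaled(VAD_A_FACTOR)
        params[POSTERIOR_IDX, 3] += e * VAD_C_POST_SHIFT
    params[:, 3] = np.clip(params[:, 3], PARAM_CLIP_LOW[3], PARAM_CLIP_HIGH[3])
    kwargs = {}
    if jitter_subject is not None:
        kwargs["jitter_subject"] = np.asarray(jitter_subject, float)
    if jitter_channel is not None:
        kwargs["jitter_channel"] = np.asarray(jitter_channel, float)
    return GroundTruthProfile(group_label, params, effect_scale=e, **kwargs)


def sample_subject(
    profile: GroundTruthProfile, seed: int, subject_id: str | None = None
) -> SubjectTruth:
    """Draw one subject's realized parameters around a group profile.

    A subject-level normal deviation (shared across channels) plus an
    independent per-channel normal deviation are added per parameter, then
    clipped to the parameter bounds. Deterministic given (profile, seed).
    """
    js = np.asarray(profile.jitter_subject, float)
    jc = np.asarray(profile.jitter_channel, float)
    if np.any(js < 0) or np.any(jc < 0) or not np.all(np.isfinite(js)) or not np.all(np.isfinite(jc)):
        raise ValueError("jitter scales must be finite and non-negative")
    rng = np.random.default_rng(seed)
    subj_dev = rng.normal(0.0, 1.0, size=N_PARAMS) * js
    chan_dev = rng.normal(0.0, 1.0, size=(N_CHANNELS, N_PARAMS)) * jc
    params = profile.params + subj_dev[None, :] + chan_dev
    params = np.clip(params, PARAM_CLIP_LOW, PARAM_CLIP_HIGH)
    sid = subject_id if subject_id is not None else f"{profile.group_label}_{seed}"
    return SubjectTruth(sid, profile.group_label, params, int(seed))


def synthesize_timeseries(
    truth: SubjectTruth,
    duration_s: float,
    fs: float = 256.0,
    artifact_rate: float = 0.0,
    seed: int = 0,
    f_max: float = 50.0,
) -> MultiChannelSignal:
    """Colored-noise EEG whose expected spectrum is the subject's model curve.

    Per channel, sinusoidal components at the signal's FFT resolution between
    0.5 Hz and ``f_max`` get deterministic amplitudes matching the target
    power (model curve interpreted as power per 0.5-Hz bin) and i.i.d. random
    phases; the inverse FFT yields the time series. With probability
    ``artifact_rate`` per second a high-amplitude transient (>= 500 µV peak)
    is added across channels.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if float(fs) not in VALID_FS:
        raise ValueError(f"fs must be one of {VALID_FS}")
    if not 0.0 <= artifact_rate <= 1.0:
        raise ValueError("artifact_rate must lie in [0, 1]")
    fs = float(fs)
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= 0.5) & (freqs <= min(f_max, fs / 2))
    fb = freqs[band]
    T = n / fs
    data = np.zeros((n, N_CHANNELS))
    if fb.size:
        # power per 0.5-Hz bin -> PSD in µV²/Hz is model/0.5; a component at
        # resolution 1/T carries a² / 2 = PSD / T of power.
        for ch in range(N_CHANNELS):
            target = model_curve(truth.params[ch], fb)  # µV² per 0.5-Hz bin
            amp = np.sqrt(np.clip(target, 0.0, None) * 2.0 / (0.5 * T))
            phases = rng.uniform(0.0, 2.0 * np.pi, size=fb.size)
            spec = np.zeros(freqs.size, dtype=complex)
            spec[band] = (n / 2.0) * amp * np.exp(1j * phases)
            data[:, ch] = np.fft.irfft(spec, n=n)

    artifact_times: list[float] = []
    if artifact_rate > 0:
        hits = rng.random(int(np.floor(duration_s))) < artifact_rate
        width = int(round(0.3 * fs))
        t = np.arange(width) / fs
        pulse = np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)  # 300-ms Gaussian transient
        for sec in np.nonzero(hits)[0]:
            start = int(sec * fs)
            stop = min(start + width, n)
            gains = 600.0 * rng.uniform(0.9, 1.3, size=N_CHANNELS)
            gains *= rng.choice([-1.0, 1.0], size=N_CHANNELS)
            data[start:stop] += pulse[: stop - start, None] * gains[None, :]
            artifact_times.append(float(sec))

    return MultiChannelSignal(data, fs, artifact_times=tuple(artifact_times))


def synthesize_spectra(truth: SubjectTruth, n_epochs: int = 334, seed: int = 0):
    """Direct spectra for one subject: model curve × Gamma Welch noise.

    Averaging ``n_epochs`` half-overlapping rectangular-window periodograms
    behaves like averaging roughly ``m = ceil(n_epochs / 2)`` independent
    ones; each 0.5-Hz bin is therefore the model power multiplied by an
    independent Gamma(m, 1/m) variate (mean 1, variance 1/m).
    """
    from .spectra import SubjectSpectra  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    m = max(int(np.ceil(n_epochs / 2)), 1)
    clean = np.vstack([model_curve(truth.params[ch], FREQ_GRID) for ch in range(N_CHANNELS)])
    noise = rng.gamma(shape=m, scale=1.0 / m, size=clean.shape)
    return SubjectSpectra(
        freqs=FREQ_GRID.copy(),
        power=clean * noise,
        n_epochs=int(n_epochs),
        subject_id=truth.subject_id,
    )


@dataclass
class CohortConfig:
    """Study-condition settings for a synthetic cohort."""

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 114
    effect_scale: float = 1.0
    mode: str = "spectra"  # "spectra" (direct) or "timeseries"
    fs: float = 256.0
    duration_s: float = 540.0  # ~9 min of resting data
    artifact_rate: float = 0.0
    n_epochs: int = 334
    jitter_subject: tuple | None = None
    jitter_channel: tuple | None = None


@dataclass
class CohortSubject:
    truth: SubjectTruth
    signal: MultiChannelSignal | None = None
    spectra: object | None = None  # SubjectSpectra in direct mode


@dataclass
class Cohort:
    subjects: list[CohortSubject]
    manifest: pd.DataFrame
    config: CohortConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.concat([s.truth.param_frame() for s in self.subjects], ignore_index=True)


def synthesize_cohort(config: CohortConfig, seed: int = 0) -> Cohort:
    """Generate a labeled cohort with equal group sizes.

    Groups are emulated as balanced (equal n per group). Fully reproducible
    from (config, seed): one master seed fans out to per-subject seeds via
    ``numpy.random.SeedSequence``.
    """
    if config.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if config.mode not in ("spectra", "timeseries"):
        raise ValueError(f"unknown cohort mode {config.mode!r}")
    profiles = {
        g: make_group_profile(
            g,
            config.effect_scale,
            jitter_subject=config.jitter_subject,
            jitter_channel=config.jitter_channel,
        )
        for g in config.groups
    }
    n_total = config.n_per_group * len(config.groups)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_total) % (2**31)
    subjects: list[CohortSubject] = []
    rows = []
    i = 0
    for g in config.groups:
        for j in range(config.n_per_group):
            sid = f"{g}{j:03d}"
            s_truth = int(child_seeds[2 * i])
            s_data = int(child_seeds[2 * i + 1])
            truth = sample_subject(profiles[g], s_truth, subject_id=sid)
            subj = CohortSubject(truth=truth)
            if config.mode == "timeseries":
                subj.signal = synthesize_timeseries(
                    truth,
                    duration_s=config.duration_s,
                    fs=config.fs,
                    artifact_rate=config.artifact_rate,
                    seed=s_data,
                )
            else:
                subj.spectra = synthesize_spectra(truth, n_epochs=config.n_epochs, seed=s_data)
            subjects.append(subj)
            rows.append({"subject": sid, "group": g, "seed": s_truth, "data_seed": s_data})
            i += 1
    manifest = pd.DataFrame(rows)
    return Cohort(subjects=subjects, manifest=manifest, config=config)
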