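"""Six-parameter spectral model of the resting EEG power spectrum and its fit.

The spectrum of a channel over 0.5-30 Hz is summarized by

    P(f) = b + S * f**(-k) + A * exp(-(f - c)**2 / (2 * w**2))

where ``S`` scales low-frequency (delta) power, ``k`` is the 1/f decay
exponent (larger k = faster drop-off), ``A``/``c``/``w`` are amplitude,
center and dispersion of the alpha peak, and ``b`` is a broadband baseline
offset. Fitting is bounded nonlinear least squares in linear power space
with a heuristic initializer and seeded jittered restarts; goodness of fit
is the usual R^2 over the fitted band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .montage import PARAM_NAMES

#: Fit band in Hz (inclusive).
FIT_BAND: tuple[float, float] = (0.5, 30.0)

#: Lower / upper bounds for (S, k, A, c, w, b).
LOWER_BOUNDS = np.array([0.0, 0.0, 0.0, 6.0, 0.3, 0.0])
UPPER_BOUNDS = np.array([np.inf, 5.0, np.inf, 14.0, 5.0, np.inf])


@dataclass
class SpectralFitParams:
    """Fitted spectral parameters for one channel.

    Units: S, A, b in µV² (power per 0.5-Hz bin); c, w in Hz; k dimensionless.
    """

    S: float
    k: float
    A: float
    c: float
    w: float
    b: float
    r2: float = float("nan")
    converged: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.k, self.A, self.c, self.w, self.b])

    @classmethod
    def from_array(cls, theta, r2=float("nan"), converged=True) -> "SpectralFitParams":
        return cls(*(float(v) for v in theta), r2=float(r2), converged=bool(converged))


def model_curve(params, freqs) -> np.ndarray:
    """Evaluate the six-parameter spectrum model at ``freqs`` (Hz, > 0).

    ``params`` is a :class:`SpectralFitParams` or a length-6 array-like in
    (S, k, A, c, w, b) order.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("model_curve requires strictly positive frequencies")
    if isinstance(params, SpectralFitParams):
        S, k, A, c, w, b = params.as_array()
    else:
        S, k, A, c, w, b = (float(v) for v in np.asarray(params, dtype=float))
    if w <= 0:
        # degenerate peak: no alpha contribution off-center
        gauss = np.where(freqs == c, 1.0, 0.0)
    else:
        gauss = np.exp(-((freqs - c) ** 2) / (2.0 * w**2))
    return b + S * freqs ** (-k) + A * gauss


def _residual_and_jac(theta, f, y):
    S, k, A, c, w, b = theta
    fk = f ** (-k)
    g = np.exp(-((f - c) ** 2) / (2.0 * w**2))
    r = b + S * fk + A * g - y
    J = np.empty((f.size, 6))
    J[:, 0] = fk
    J[:, 1] = -S * fk * np.log(f)
    J[:, 2] = g
    J[:, 3] = A * g * (f - c) / w**2
    J[:, 4] = A * g * (f - c) ** 2 / w**3
    J[:, 5] = 1.0
    return r, J


def goodness_of_fit(freqs, power, params, band: tuple[float, float] = FIT_BAND) -> float:
    """R² of the model over ``band``: 1 - SS_resid / SS_total.

    Raises on a zero-variance spectrum, for which R² is undefined.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    m = (freqs >= band[0]) & (freqs <= band[1])
    y = power[m]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a zero-variance spectrum")
    yhat = model_curve(params, freqs[m])
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _initial_guess(f, y):
    # baseline from the high end of the fit band
    hi = f >= 25.0
    b0 = float(np.min(y[hi])) if hi.any() else float(np.min(y))
    b0 = max(b0, 0.0)
    resid = np.clip(y - b0, 1e-12, None)
    # 1/f exponent from a log-log regression over 1-30 Hz
    m = f >= 1.0
    k0 = 1.0
    if m.sum() >= 2:
        slope = np.polyfit(np.log(f[m]), np.log(resid[m]), 1)[0]
        k0 = float(np.clip(-slope, 0.0, 5.0))
    i1 = int(np.argmin(np.abs(f - 1.0)))
    S0 = max(float(y[i1] - b0), 1e-6)
    # alpha guess from the residual after the aperiodic guess
    aper = b0 + S0 * f ** (-k0)
    alpha_band = (f >= 7.0) & (f <= 13.0)
    r_alpha = (y - aper)[alpha_band]
    if r_alpha.size:
        j = int(np.argmax(r_alpha))
        c0 = float(f[alpha_band][j])
        A0 = max(float(r_alpha[j]), 1e-6)
    else:
        c0, A0 = 10.0, 1e-6
    c0 = float(np.clip(c0, LOWER_BOUNDS[3], UPPER_BOUNDS[3]))
    return np.array([S0, k0, A0, c0, 1.5, b0])


def _clip_to_bounds(theta):
    eps = 1e-9
    lo = np.where(np.isfinite(LOWER_BOUNDS), LOWER_BOUNDS, -np.inf)
    hi = np.where(np.isfinite(UPPER_BOUNDS), UPPER_BOUNDS, np.inf)
    return np.clip(theta, lo + eps, np.where(np.isfinite(hi), hi - eps, hi))


def fit_spectrum(
    freqs,
    power,
    band: tuple[float, float] = FIT_BAND,
    n_restarts: int = 4,
    r2_accept: float = 0.95,
    space: str = "linear",
    seed: int = 0,
) -> SpectralFitParams:
    """Fit the six-parameter model to one channel's average spectrum.

    Bounded trust-region least squares over ``band`` (0.5-30 Hz by default,
    60 grid points). The heuristic initial guess is refined first; if the
    resulting R² falls below ``r2_accept``, up to ``n_restarts`` jittered
    restarts (deterministic from ``seed``) are tried and the best-R² solution
    kept. Poor fits never raise: the best attempt is returned with
    ``converged=False``.

    ``space="log"`` fits residuals of log-power instead (optional variant;
    R² is still reported in linear power space).
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    if not np.all(np.isfinite(power)):
        raise ValueError("spectrum contains non-finite values")
    if freqs.min() > band[0] or freqs.max() < band[1]:
        raise ValueError(f"spectrum must cover the fit band {band}")
    m = (freqs >= band[0]) & (freqs <= band[1])
    f, y = freqs[m], power[m]

    if space == "log":
        eps = 1e-12

        def fun(theta):
            r, J = _residual_and_jac(theta, f, y)
            p = r + y  # model values
            return np.log(p + eps) - np.log(y + eps)

        jac = "2-point"
    elif space == "linear":

        def fun(theta):
            return _residual_and_jac(theta, f, y)[0]

        def jac(theta):
            return _residual_and_jac(theta, f, y)[1]

    else:
        raise ValueError(f"unknown fit space {space!r}")

    rng = np.random.default_rng(seed)
    theta0 = _clip_to_bounds(_initial_guess(f, y))
    best = None
    best_r2 = -np.inf
    best_ok = False
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def try_start(theta_init):
        nonlocal best, best_r2, best_ok
        try:
            res = least_squares(
                fun, theta_init, jac=jac, bounds=(LOWER_BOUNDS, UPPER_BOUNDS),
                method="trf", x_scale="jac", max_nfev=400,
            )
        except Exception:
            return
        yhat = model_curve(res.x, f)
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        if r2 > best_r2:
            best, best_r2, best_ok = res.x, r2, bool(res.success)

    try_start(theta0)
    if best_r2 < r2_accept:
        for _ in range(n_restarts):
            jitter = theta0.copy()
            jitter[[0, 2, 5]] *= rng.lognormal(0.0, 0.5, size=3)  # S, A, b
            jitter[1] += rng.normal(0.0, 0.4)                      # k
            jitter[3] += rng.normal(0.0, 1.5)                      # c
            jitter[4] += rng.normal(0.0, 0.7)                      # w
            try_start(_clip_to_bounds(jitter))
            if best_r2 >= r2_accept:
                break

    if best is None:  # pragma: no cover - optimizer failure on all starts
        return SpectralFitParams.from_array(theta0, r2=-np.inf, converged=False)
    converged = best_ok and np.all(np.isfinite(best))
    return SpectralFitParams.from_array(best, r2=best_r2, converged=converged)


def param_correlations(fits: pd.DataFrame, by: str | None = None) -> pd.DataFrame | dict:
    """Pearson correlations between the six fitted parameters.

    ``fits`` is a long table with one row per (subject, channel) fit and the
    six parameter columns. With ``by=None`` the pooled 6×6 correlation matrix
    is returned; with ``by="group"`` (or any column name) a dict mapping each
    level to its matrix. Constant columns yield NaN entries (correlation
    undefined).

    Lets users audit parameter redundancy — e.g. the k-b coupling both
    parameters exert on the high-frequency floor.
    """
    cols = list(PARAM_NAMES)
    if by is None:
        if len(fits) < 3:
            raise ValueError("need at least 3 fits for correlations")
        return fits[cols].corr()
    return {lvl: sub[cols].corr() for lvl, sub in fits.groupby(by)}
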