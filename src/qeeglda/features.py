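"""Predictor assembly, Box-Cox normalization and correlation screening.

Each subject contributes 6 spectral parameters × 22 channels = 132
predictors, laid out channel-major (all six parameters of Fp1, then Fpz,
...). Before discriminant training the columns are mapped toward normality
with a per-column Box-Cox transform, and in the reduced-feature mode columns
weakly correlated with the class labels are screened out. Both the transform
and the screening use training rows only, so no information leaks from
held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .montage import CHANNELS, PARAM_NAMES

N_FEATURES = len(CHANNELS) * len(PARAM_NAMES)  # 132


def feature_columns() -> list[str]:
    """Column names in canonical channel-major, parameter-minor order."""
    return [f"{ch}_{p}" for ch in CHANNELS for p in PARAM_NAMES]


@dataclass
class BoxCoxRecord:
    """Per-column Box-Cox parameters fitted on training rows."""

    lmbda: np.ndarray      # (p,)
    shift: np.ndarray      # (p,) added before the power transform
    identity: np.ndarray   # (p,) bool: column passed through untransformed


@dataclass
class FeatureMatrix:
    """Subjects × 132 predictor table with labels and column metadata."""

    X: np.ndarray
    labels: np.ndarray
    columns: list[str] = field(default_factory=feature_columns)
    subjects: list[str] | None = None
    transform: BoxCoxRecord | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X rows must match labels")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column metadata must match the matrix width")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature values must be finite")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "label", self.labels)
        if self.subjects is not None:
            df.insert(0, "subject", self.subjects)
        return df


@dataclass
class ScreenResult:
    """Per-column point-biserial correlation screen against binary labels."""

    r: np.ndarray
    p: np.ndarray
    keep: np.ndarray
    r_min: float
    alpha: float
    rule: str


def build_feature_matrix(fits: pd.DataFrame, labels: pd.Series) -> FeatureMatrix:
    """Assemble the subjects × 132 matrix from a long fit table.

    ``fits`` has one row per (subject, channel) with the six parameter
    columns; ``labels`` is indexed by subject id and fixes the row order.
    Every subject must have a fit for all 22 channels.
    """
    cols = feature_columns()
    wide = fits.pivot_table(index="subject", columns="channel",
                            values=list(PARAM_NAMES), aggfunc="first")
    rows = []
    for sid in labels.index:
        if sid not in wide.index:
            raise ValueError(f"no fits for subject {sid!r}")
        sub = wide.loc[sid]
        vals = []
        for ch in CHANNELS:
            for p in PARAM_NAMES:
                v = sub.get((p, ch), np.nan)
                if pd.isna(v):
                    raise ValueError(f"missing channel fit {ch!r} for subject {sid!r}")
                vals.append(float(v))
        rows.append(vals)
    return FeatureMatrix(
        X=np.array(rows), labels=labels.to_numpy(),
        columns=cols, subjects=list(labels.index),
    )


def boxcox_mle_lambda(x: np.ndarray, bounds: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Box-Cox λ by maximizing the profile log-likelihood.

    For positive data x, llf(λ) = (λ-1)·Σ log x - n/2·log Var[y_λ(x)] with
    y_λ the Box-Cox transform; maximized by a bounded scalar search. Agrees
    with scipy.stats.boxcox's ML estimate but is fast enough to be refitted
    on every training fold of a repeated CV.
    """
    from scipy.optimize import minimize_scalar

    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    logx = np.log(x)
    slog = logx.sum()
    n = x.size

    def neg_llf(lm):
        y = special.boxcox(x, lm)
        v = y.var()
        if not np.isfinite(v) or v <= 0:
            return np.inf
        return -((lm - 1.0) * slog - 0.5 * n * np.log(v))

    res = minimize_scalar(neg_llf, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def boxcox_transform(
    X: np.ndarray, train_rows: np.ndarray, eps: float = 1e-6
) -> tuple[np.ndarray, BoxCoxRecord]:
    """Column-wise Box-Cox with λ estimated by ML on training rows only.

    Columns with non-positive training values get a recorded shift
    ``eps - min``; the same (λ, shift) is applied to every row (held-out
    values that remain non-positive after the shift are clipped to ``eps``).
    Zero-variance training columns pass through unchanged and are flagged.
    λ = 0 is the natural log branch.
    """
    X = np.asarray(X, float)
    train_rows = np.asarray(train_rows)
    p = X.shape[1]
    lmbda = np.zeros(p)
    shift = np.zeros(p)
    identity = np.zeros(p, dtype=bool)
    Xt = np.empty_like(X)
    for j in range(p):
        tr = X[train_rows, j]
        if np.ptp(tr) == 0:
            identity[j] = True
            Xt[:, j] = X[:, j]
            continue
        mn = tr.min()
        sj = 0.0 if mn > 0 else eps - mn
        xs = tr + sj
        try:
            lj = boxcox_mle_lambda(xs)
        except Exception:
            identity[j] = True
            Xt[:, j] = X[:, j]
            continue
        lmbda[j], shift[j] = float(lj), float(sj)
        Xt[:, j] = special.boxcox(np.clip(X[:, j] + sj, eps, None), lj)
    return Xt, BoxCoxRecord(lmbda=lmbda, shift=shift, identity=identity)


def apply_boxcox(X: np.ndarray, record: BoxCoxRecord, eps: float = 1e-6) -> np.ndarray:
    """Apply a previously fitted Box-Cox record to new rows."""
    X = np.asarray(X, float)
    Xt = np.empty_like(X)
    for j in range(X.shape[1]):
        if record.identity[j]:
            Xt[:, j] = X[:, j]
        else:
            Xt[:, j] = special.boxcox(
                np.clip(X[:, j] + record.shift[j], eps, None), record.lmbda[j]
            )
    return Xt


def screen_features(
    X: np.ndarray,
    y: np.ndarray,
    train_rows: np.ndarray,
    r_min: float = 0.15,
    alpha: float = 0.01,
    rule: str = "r_only",
) -> ScreenResult:
    """Point-biserial correlation screen computed on training rows only.

    For each column, Pearson r against the 0/1 labels and the two-tailed
    p-value from t = r·sqrt((n-2)/(1-r²)) on n-2 degrees of freedom.
    ``rule="r_only"`` (default) keeps a column iff |r| >= ``r_min``;
    ``rule="r_and_p"`` additionally requires p < ``alpha``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    tr = np.asarray(train_rows)
    yt = y[tr]
    if np.unique(yt).size < 2:
        raise ValueError("training rows must contain both classes")
    Xt = X[tr]
    n = Xt.shape[0]
    xc = Xt - Xt.mean(axis=0)
    yc = yt - yt.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(sx > 0, r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    if rule == "r_only":
        keep = np.abs(r) >= r_min
    elif rule == "r_and_p":
        keep = (np.abs(r) >= r_min) & (p < alpha)
    else:
        raise ValueError(f"unknown screening rule {rule!r}")
    return ScreenResult(r=r, p=p, keep=keep, r_min=r_min, alpha=alpha, rule=rule)
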