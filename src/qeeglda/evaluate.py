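"""Cross-validated evaluation: 10-fold CV with in-fold screening, 20-repeat
re-randomized CV, ROC/AUC and a Table-shaped four-model summary.

Per fold, the Box-Cox transform and (in reduced mode) the correlation screen
are fitted on the training rows only, then an RLDA is trained and scored on
the held-out fold. "Bootstrap" robustness follows the source protocol:
20 repetitions of the whole CV, each with a freshly randomized fold
assignment (true resampling with replacement is available but off by
default). AUC comes from each repeat's pooled held-out scores via a
threshold sweep whose trapezoid area equals the Mann-Whitney U statistic;
ROC curves are vertically averaged on a fixed FPR grid with an SEM band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FeatureMatrix, apply_boxcox, boxcox_transform, screen_features
from .rlda import decision_scores, fit_rlda

MODEL_CONTRASTS = {
    "Model 1 (HC vs. AD)": (("HC",), ("AD",)),
    "Model 2 (HC vs. VaD)": (("HC",), ("VaD",)),
    "Model 3 (AD vs. VaD)": (("AD",), ("VaD",)),
    "Model 4 (HC vs. AD&VaD)": (("HC",), ("AD", "VaD")),
}


@dataclass
class CvConfig:
    """Evaluation settings: 10 folds, 20 repeats, in-fold screening."""

    k: int = 10
    n_repeats: int = 20
    stratified: bool = True
    boxcox: str | None = "per_fold"   # "per_fold", "global", or None
    r_min: float = 0.15
    alpha: float = 0.01
    screen_rule: str = "r_only"
    shrinkage: float | str = "analytic"
    resample: bool = False            # true bootstrap resampling per repeat
    fpr_grid_points: int = 101


@dataclass
class FoldResult:
    """Held-out metrics and scores for one CV fold."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected: np.ndarray
    acc: float
    tpr: float
    fpr: float
    scores: np.ndarray
    truth: np.ndarray


@dataclass
class RocCurve:
    """ROC operating points from a threshold sweep, with trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class RepeatSummary:
    """Mean/SEM of cv-ACC and AUC over repeated CV, plus the averaged ROC."""

    cv_accs: np.ndarray
    aucs: np.ndarray
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sem_tpr: np.ndarray

    @property
    def mean_cv_acc(self) -> float:
        return float(self.cv_accs.mean())

    @property
    def sem_cv_acc(self) -> float:
        return _sem(self.cv_accs)

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sem_auc(self) -> float:
        return _sem(self.aucs)


@dataclass
class PerformanceSummary:
    """Four-model × feature-set performance table with the ROC summaries."""

    table: pd.DataFrame
    repeats: dict = field(default_factory=dict)  # (model, mode) -> RepeatSummary


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def kfold_split(n: int, k: int = 10, seed: int = 0, y=None, stratified: bool = True):
    """Randomized near-equal folds (sizes differ by at most 1).

    Returns a list of test-index arrays partitioning ``range(n)``. With
    ``stratified=True`` (default) and labels ``y``, class proportions are
    preserved per fold, which also guarantees both classes in every training
    set at the study's sample sizes.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    seed = int(seed) % (2**31)
    if stratified and y is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), np.asarray(y))]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def roc_and_auc(scores, truth) -> RocCurve:
    """ROC by threshold sweep; trapezoid AUC (= Mann-Whitney U / (n₀ n₁)).

    Tied scores collapse onto single operating points, which makes the
    trapezoid area identical to the midrank Mann-Whitney statistic.
    """
    from sklearn.metrics import roc_curve

    truth = np.asarray(truth)
    scores = np.asarray(scores, float)
    if np.unique(truth).size < 2:
        raise ValueError("ROC needs both classes in truth")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "complete",
    config: CvConfig | None = None,
    seed: int = 0,
) -> list[FoldResult]:
    """One pass of k-fold CV with per-fold transform/screen/fit/score.

    ``mode="complete"`` uses all 132 columns; ``mode="reduced"`` screens
    columns on each training fold before fitting. Positive class is label 1.
    """
    if mode not in ("complete", "reduced"):
        raise ValueError(f"unknown feature-set mode {mode!r}")
    cfg = config or CvConfig()
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    folds = kfold_split(n, cfg.k, seed=seed, y=y, stratified=cfg.stratified)
    all_idx = np.arange(n)

    X_global = X
    if cfg.boxcox == "global":
        X_global, _ = boxcox_transform(X, all_idx)

    results: list[FoldResult] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(f"training fold {i} lost a class; use stratified folds")
        if cfg.boxcox == "per_fold":
            _, record = boxcox_transform(X[train_idx], np.arange(train_idx.size))
            Xt_train = apply_boxcox(X[train_idx], record)
            Xt_test = apply_boxcox(X[test_idx], record)
        else:
            Xt_train = X_global[train_idx]
            Xt_test = X_global[test_idx]

        if mode == "reduced":
            screen = screen_features(
                Xt_train, y[train_idx], np.arange(train_idx.size),
                r_min=cfg.r_min, alpha=cfg.alpha, rule=cfg.screen_rule,
            )
            selected = np.nonzero(screen.keep)[0]
            if selected.size == 0:  # keep the single strongest column
                selected = np.array([int(np.argmax(np.abs(screen.r)))])
        else:
            selected = np.arange(X.shape[1])

        model = fit_rlda(Xt_train[:, selected], y[train_idx], shrinkage=cfg.shrinkage)
        scores = decision_scores(model, Xt_test[:, selected])
        truth = y[test_idx]
        pred = scores > 0
        acc = float(np.mean(pred == (truth == 1)))
        pos = truth == 1
        tpr = float(np.mean(pred[pos])) if pos.any() else float("nan")
        fpr = float(np.mean(pred[~pos])) if (~pos).any() else float("nan")
        results.append(FoldResult(
            fold=i, train_idx=train_idx, test_idx=test_idx, selected=selected,
            acc=acc, tpr=tpr, fpr=fpr, scores=scores, truth=truth,
        ))
    return results


def repeat_cv(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "complete",
    config: CvConfig | None = None,
    seed: int = 0,
    n_repeats: int | None = None,
    repeat_seeds=None,
) -> RepeatSummary:
    """Repeat the full CV with re-randomized folds and summarize.

    Per repeat: cv-ACC = mean held-out fold accuracy; AUC from the repeat's
    pooled held-out scores. The summary reports mean and SEM over repeats and
    the vertically averaged ROC (TPR interpolated on a fixed FPR grid).
    ``repeat_seeds`` overrides the per-repeat fold seeds (len = repeats).
    """
    cfg = config or CvConfig()
    R = n_repeats if n_repeats is not None else cfg.n_repeats
    rng = np.random.default_rng(seed)
    if repeat_seeds is not None:
        repeat_seeds = np.asarray(repeat_seeds, int)
        R = repeat_seeds.size
    else:
        repeat_seeds = rng.integers(0, 2**31, size=R)
    grid = np.linspace(0.0, 1.0, cfg.fpr_grid_points)
    cv_accs, aucs, tprs = [], [], []
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    for r in range(R):
        Xr, yr = X, y
        if cfg.resample:
            idx = rng.integers(0, X.shape[0], size=X.shape[0])
            Xr, yr = X[idx], y[idx]
        folds = run_cv(Xr, yr, mode=mode, config=cfg, seed=int(repeat_seeds[r]))
        cv_accs.append(float(np.mean([f.acc for f in folds])))
        scores = np.concatenate([f.scores for f in folds])
        truth = np.concatenate([f.truth for f in folds])
        roc = roc_and_auc(scores, truth)
        aucs.append(roc.auc)
        tprs.append(np.interp(grid, roc.fpr, roc.tpr))
    tprs = np.asarray(tprs)
    return RepeatSummary(
        cv_accs=np.asarray(cv_accs), aucs=np.asarray(aucs), fpr_grid=grid,
        mean_tpr=tprs.mean(axis=0),
        sem_tpr=tprs.std(ddof=1, axis=0) / np.sqrt(R) if R > 1 else np.zeros(grid.size),
    )


def make_contrast(features: FeatureMatrix, negative: tuple, positive: tuple):
    """Select rows for a binary contrast; returns (X, y01) with positives = 1."""
    groups = np.asarray(features.labels)
    mask = np.isin(groups, negative + positive)
    y = np.isin(groups[mask], positive).astype(int)
    return features.X[mask], y


def summarize_models(
    features: FeatureMatrix,
    config: CvConfig | None = None,
    seed: int = 0,
    modes: tuple[str, ...] = ("complete", "reduced"),
    models: tuple[str, ...] | None = None,
) -> PerformanceSummary:
    """Run the four diagnostic contrasts under each feature-set mode.

    ``features.labels`` must hold the group names (HC/AD/VaD). Model 4 pools
    AD and VaD as the positive class against HC. The result table has one
    row per model and (mode × {cv-ACC, AUC, SEMs}) columns.
    """
    cfg = config or CvConfig()
    names = models if models is not None else tuple(MODEL_CONTRASTS)
    present = set(np.asarray(features.labels).tolist())
    rows = {}
    repeats = {}
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(len(names) * len(modes)) % (2**31))
    for name in names:
        neg, pos = MODEL_CONTRASTS[name]
        missing = [g for g in neg + pos if g not in present]
        if missing:
            raise ValueError(f"{name}: missing group(s) {missing}")
        Xc, yc = make_contrast(features, neg, pos)
        row = {}
        for mode in modes:
            summ = repeat_cv(Xc, yc, mode=mode, config=cfg, seed=int(next(child)))
            repeats[(name, mode)] = summ
            row[(mode, "cv_acc")] = summ.mean_cv_acc
            row[(mode, "sem_cv_acc")] = summ.sem_cv_acc
            row[(mode, "auc")] = summ.mean_auc
            row[(mode, "sem_auc")] = summ.sem_auc
        rows[name] = row
    table = pd.DataFrame(rows).T
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return PerformanceSummary(table=table, repeats=repeats)
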