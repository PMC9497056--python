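"""The two classifier tracks.

SVM track: 7:3 stratified split, z-score normalization fit on the training
rows, RBF-kernel SVC with an exhaustive 81-point grid over
C, gamma in {2^-4 .. 2^4}, scored by mean 5-fold stratified CV accuracy.

GBDT track: 8:2 stratified split, per-feature Welch t-test selection
(p < alpha) followed by normalization, gradient-boosted trees with a small
5-fold CV-selected grid (trees in {50, 100, 200}, depth in {2, 3}).

Scaler and selection statistics are always fit on training rows only.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC

from .errors import ContractError, SelectionError, SplitError
from .features import FeatureTable

_HANDLE_VERSION = 1


@dataclass
class SplitSpec:
    """Stratified train/test partition; 0.7 for the SVM track, 0.8 for GBDT.

    ``unit='recording'`` splits rows directly (plain random stratified
    sampling, which lets recordings of one subject span train and test);
    ``unit='subject'`` stratifies whole subjects so no identity leaks
    across the partition — the stricter protocol for clinical claims.
    """

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0
    unit: str = "recording"


@dataclass
class SVMGrid:
    """Powers-of-two grid: 9 x 9 = 81 (C, gamma) candidates, 5-fold CV."""

    C_exponents: Sequence[int] = tuple(range(-4, 5))
    gamma_exponents: Sequence[int] = tuple(range(-4, 5))
    base: float = 2.0
    k_folds: int = 5


@dataclass
class GBDTParams:
    learning_rate: float = 0.1
    n_estimators_grid: Sequence[int] = (50, 100, 200)
    max_depth_grid: Sequence[int] = (2, 3)
    k_folds: int = 5


@dataclass
class ScalerParams:
    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str]


@dataclass
class SelectionMask:
    keep: np.ndarray              # boolean per feature
    t_statistic: np.ndarray
    p_value: np.ndarray
    feature_names: list[str]

    @property
    def kept_names(self) -> list[str]:
        return [n for n, k in zip(self.feature_names, self.keep) if k]


@dataclass
class ModelHandle:
    """Fitted classifier plus the preprocessing fitted with it."""

    track: str                       # "SVM" or "GBDT"
    model: object
    scaler: ScalerParams
    mask: SelectionMask | None
    hyperparameters: dict
    cv_table: pd.DataFrame
    feature_names: list[str]
    version: int = _HANDLE_VERSION

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ModelHandle":
        with open(path, "rb") as fh:
            handle = pickle.load(fh)
        if not isinstance(handle, ModelHandle):
            raise ContractError(f"{path} is not a model handle")
        return handle


# ---------------------------------------------------------------------------
# splitting / scaling / selection
# ---------------------------------------------------------------------------

def stratified_split(table: FeatureTable, spec: SplitSpec
                     ) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive partition preserving class proportions within
    one sample per class; deterministic given ``spec.seed``."""
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SplitError("both classes must be present")
    if counts.min() < 2:
        raise SplitError("each class needs at least 2 rows to split")
    if spec.unit == "subject":
        subjects = table.frame["subject_id"].to_numpy()
        uniq, first = np.unique(subjects, return_index=True)
        sub_labels = y[first]
        if min(np.bincount(sub_labels)) < 2:
            raise SplitError("each class needs at least 2 subjects to split")
        tr_sub, _ = train_test_split(
            uniq, train_size=spec.train_fraction, random_state=spec.seed,
            shuffle=True, stratify=sub_labels if spec.stratified else None)
        in_train = np.isin(subjects, tr_sub)
        train_idx = np.flatnonzero(in_train)
        test_idx = np.flatnonzero(~in_train)
    elif spec.unit == "recording":
        idx = np.arange(len(table))
        train_idx, test_idx = train_test_split(
            idx, train_size=spec.train_fraction, random_state=spec.seed,
            shuffle=True, stratify=y if spec.stratified else None)
    else:
        raise SplitError(f"unknown split unit {spec.unit!r}")
    train = FeatureTable(table.frame.iloc[np.sort(train_idx)].reset_index(drop=True))
    test = FeatureTable(table.frame.iloc[np.sort(test_idx)].reset_index(drop=True))
    return train, test


def fit_scaler(X: np.ndarray, feature_names: list[str]) -> ScalerParams:
    """Z-score parameters from training rows; zero-variance features get
    scale 1 (they become constant 0) with a warning."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale <= 1e-12 * (np.abs(mean) + 1.0)
    if np.any(zero):
        bad = [feature_names[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance feature(s) {bad}: scale set to 1")
        scale = np.where(zero, 1.0, scale)
    return ScalerParams(mean=mean, scale=scale, feature_names=list(feature_names))


def apply_scaler(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.mean) / params.scale


def ttest_select(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                 alpha: float = 0.05) -> SelectionMask:
    """Welch two-sample t-test per feature; keep p < alpha, falling back to
    the single smallest-p feature if nothing survives."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("t-test selection needs both classes")
    X = np.asarray(X, dtype=float)
    a, b = X[y == 1], X[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    keep = p < alpha
    if not np.any(keep):
        keep = np.zeros_like(keep)
        keep[int(np.argmin(p))] = True
    return SelectionMask(keep=keep, t_statistic=t, p_value=p,
                         feature_names=list(feature_names))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_svm(train: FeatureTable, grid: SVMGrid | None = None,
              seed: int = 0) -> ModelHandle:
    """Exhaustive (C, gamma) grid search with 5-fold stratified CV.

    Ties in mean CV accuracy break toward smaller C, then smaller gamma
    (the smoothest model); the winner is refit on the full training rows.
    """
    grid = grid or SVMGrid()
    names = train.feature_names
    scaler = fit_scaler(train.X, names)
    Xs, y = apply_scaler(train.X, scaler), train.labels
    cv = StratifiedKFold(n_splits=grid.k_folds, shuffle=True, random_state=seed)
    rows = []
    best = None  # (acc, C, gamma); iteration order implements the tie rule
    for j in grid.C_exponents:
        for i in grid.gamma_exponents:
            C, gamma = grid.base ** j, grid.base ** i
            acc = float(np.mean(cross_val_score(
                SVC(C=C, gamma=gamma, kernel="rbf"), Xs, y, cv=cv,
                scoring="accuracy")))
            rows.append({"C_exponent": j, "gamma_exponent": i,
                         "C": C, "gamma": gamma, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    _, C, gamma = best
    model = SVC(C=C, gamma=gamma, kernel="rbf").fit(Xs, y)
    return ModelHandle(track="SVM", model=model, scaler=scaler, mask=None,
                       hyperparameters={"C": C, "gamma": gamma,
                                        "cv_accuracy": best[0]},
                       cv_table=pd.DataFrame(rows), feature_names=names)


def train_gbdt(train: FeatureTable, params: GBDTParams | None = None,
               seed: int = 0, alpha: float = 0.05) -> ModelHandle:
    """t-test feature selection, normalization, then a small CV-selected
    gradient-boosting grid; ties break toward the smaller ensemble."""
    params = params or GBDTParams()
    names = train.feature_names
    y = train.labels
    mask = ttest_select(train.X, y, names, alpha=alpha)
    Xsel = train.X[:, mask.keep]
    scaler = fit_scaler(Xsel, mask.kept_names)
    Xs = apply_scaler(Xsel, scaler)
    cv = StratifiedKFold(n_splits=params.k_folds, shuffle=True, random_state=seed)
    rows = []
    best = None
    for n_est in params.n_estimators_grid:
        for depth in params.max_depth_grid:
            clf = GradientBoostingClassifier(
                learning_rate=params.learning_rate, n_estimators=n_est,
                max_depth=depth, random_state=seed)
            acc = float(np.mean(cross_val_score(clf, Xs, y, cv=cv,
                                                scoring="accuracy")))
            rows.append({"n_estimators": n_est, "max_depth": depth,
                         "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, n_est, depth)
    _, n_est, depth = best
    model = GradientBoostingClassifier(
        learning_rate=params.learning_rate, n_estimators=n_est,
        max_depth=depth, random_state=seed).fit(Xs, y)
    return ModelHandle(track="GBDT", model=model, scaler=scaler, mask=mask,
                       hyperparameters={"n_estimators": n_est,
                                        "max_depth": depth,
                                        "learning_rate": params.learning_rate,
                                        "cv_accuracy": best[0]},
                       cv_table=pd.DataFrame(rows), feature_names=names)


def predict(handle: ModelHandle, rows: FeatureTable
            ) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) for new rows, applying the handle's own selection
    and scaling.  Scores are the SVM margin or the GBDT positive-class
    probability — monotone in positive-class confidence either way."""
    missing = [n for n in handle.feature_names if n not in rows.feature_names]
    if missing:
        raise ContractError(f"rows lack trained features: {missing}")
    if len(rows) == 0:
        return np.array([], dtype=int), np.array([], dtype=float)
    X = rows.frame[handle.feature_names].to_numpy(dtype=float)
    if handle.mask is not None:
        X = X[:, handle.mask.keep]
    Xs = apply_scaler(X, handle.scaler)
    labels = handle.model.predict(Xs).astype(int)
    if isinstance(handle.model, SVC):
        scores = handle.model.decision_function(Xs)
    else:
        scores = handle.model.predict_proba(Xs)[:, 1]
    return labels, np.asarray(scores, dtype=float)


def cv_pooled_scores(table: FeatureTable, track: str, seed: int = 0,
                     n_folds: int = 5
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Held-out scores for every row via an outer stratified K-fold.

    Each outer training fold reruns the full track protocol (selection,
    scaling, inner-CV hyperparameter search), so the pooled scores are
    leakage-free.  Returns (labels, scores, predictions) aligned with the
    table rows.
    """
    if track not in ("SVM", "GBDT"):
        raise ContractError(f"unknown track {track!r}")
    y = table.labels
    scores = np.empty(len(table), dtype=float)
    preds = np.empty(len(table), dtype=int)
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(outer.split(np.zeros(len(table)), y)):
        sub = FeatureTable(table.frame.iloc[tr].reset_index(drop=True))
        if track == "SVM":
            handle = train_svm(sub, seed=seed + k)
        else:
            handle = train_gbdt(sub, seed=seed + k)
        p, s = predict(handle, FeatureTable(
            table.frame.iloc[te].reset_index(drop=True)))
        scores[te] = s
        preds[te] = p
    return y, scores, preds
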