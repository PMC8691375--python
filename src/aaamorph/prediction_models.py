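"""Growth prediction models: multinomial logistic and linear regression.

The cohort is split once into training and testing sets.  On the training
set a small ridge-style regularization grid is tuned by k-fold
cross-validation (stratified folds for the 3-class logistic model,
standardization refit inside every fold to avoid leakage); the strength
minimizing mean validation loss (deviance for logistic, RMSE for linear) is
selected and the model refit on all training rows.  Evaluation on the held
out test set reports one-vs-rest ROC/AUROC for the slow and fast growth
categories (logistic) or RMSE, correlation and the fraction of predictions
within a +/-2 mm/yr margin (linear).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from scipy import stats

from .geometry_features import RC_CAP_MM
from .growth_analysis import CATEGORIES

log = logging.getLogger(__name__)

FEATURE_NAMES = ("apd", "ui", "min_rc")

_COLUMN_OF = {
    "apd": "apd_baseline_mm",
    "ui": "ui_baseline",
    "min_rc": "min_rc_baseline_mm",
}

#: Regularization strengths tried during cross-validation (ridge alpha on
#: standardized features; 0 = plain least squares / effectively
#: unregularized logistic).
DEFAULT_STRENGTH_GRID = (0.0, 0.01, 0.1, 1.0, 10.0)


@dataclass
class ModelSpec:
    """What to fit: model family, feature subset, CV protocol."""

    model_kind: str  # "multinomial_logistic" | "linear"
    features: tuple[str, ...] = FEATURE_NAMES
    cv_folds: int = 10
    seed: int = 0
    strength_grid: tuple[float, ...] = DEFAULT_STRENGTH_GRID

    def __post_init__(self) -> None:
        if self.model_kind not in ("multinomial_logistic", "linear"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        self.features = tuple(self.features)
        if not self.features:
            raise ValueError("feature subset must be non-empty")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class FitResult:
    """A fitted model plus its CV diagnostics."""

    spec: ModelSpec
    scaler: StandardScaler
    model: object
    best_strength: float
    cv_summary: pd.DataFrame  # columns: strength, fold, loss
    coefficients: dict = field(default_factory=dict)  # original (mm) scale
    coef_se: dict | None = None  # linear only: OLS standard errors


class SingleClassError(ValueError):
    """Test set contains only one class for the requested binarization."""


def design_matrix(frame: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Feature columns as a float matrix, with min RC capped to stay finite."""
    cols = []
    for f in features:
        x = frame[_COLUMN_OF[f]].to_numpy(dtype=float)
        if f == "min_rc":
            x = np.minimum(x, RC_CAP_MM)
        cols.append(x)
    return np.column_stack(cols)


def split_cohort(frame: pd.DataFrame, n_train: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible random split into disjoint, exhaustive train/test sets."""
    n = len(frame)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = frame.iloc[order[:n_train]].reset_index(drop=True)
    test = frame.iloc[order[n_train:]].reset_index(drop=True)
    return train, test


def _make_model(kind: str, strength: float, seed: int):
    if kind == "linear":
        if strength == 0.0:
            return LinearRegression()
        return Ridge(alpha=strength)
    c = 1e8 if strength == 0.0 else 1.0 / strength
    return LogisticRegression(C=c, max_iter=2000, random_state=seed)


def _deviance(model, x: np.ndarray, y: np.ndarray) -> float:
    """Mean multinomial deviance, -2 * mean log predicted probability."""
    proba = model.predict_proba(x)
    idx = np.searchsorted(model.classes_, y)
    p = np.clip(proba[np.arange(len(y)), idx], 1e-12, None)
    return float(-2.0 * np.mean(np.log(p)))


def fit_with_cv(spec: ModelSpec, train: pd.DataFrame) -> FitResult:
    """Tune the regularization strength by k-fold CV and refit on all rows.

    Features are z-scored on the statistics of each fold's training part
    (and of the full training set for the final refit).  The reported
    coefficients are mapped back to the original mm / dimensionless scale.
    """
    if len(train) < spec.cv_folds:
        raise ValueError("training set smaller than the number of folds")
    x_all = design_matrix(train, spec.features)
    if np.any(np.ptp(x_all, axis=0) == 0):
        bad = [f for f, r in zip(spec.features, np.ptp(x_all, axis=0)) if r == 0]
        raise ValueError(f"degenerate design: constant feature(s) {bad}")
    if spec.model_kind == "linear":
        y_all = train["annual_growth_mm_yr"].to_numpy(dtype=float)
        folds = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
        split_iter = list(folds.split(x_all))
    else:
        y_all = train["category"].to_numpy(dtype=object)
        # stratified folds: with 3 classes on ~100 rows an unstratified fold
        # can easily miss a class entirely
        folds = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
        split_iter = list(folds.split(x_all, y_all))

    rows = []
    for strength in spec.strength_grid:
        for k, (tr, va) in enumerate(split_iter):
            scaler = StandardScaler().fit(x_all[tr])
            model = _make_model(spec.model_kind, strength, spec.seed)
            model.fit(scaler.transform(x_all[tr]), y_all[tr])
            if spec.model_kind == "linear":
                pred = model.predict(scaler.transform(x_all[va]))
                loss = float(np.sqrt(np.mean((pred - y_all[va].astype(float)) ** 2)))
            else:
                loss = _deviance(model, scaler.transform(x_all[va]), y_all[va])
            rows.append({"strength": strength, "fold": k, "loss": loss})
    cv_summary = pd.DataFrame(rows)
    mean_loss = cv_summary.groupby("strength")["loss"].mean()
    # ties break toward the weaker penalty
    best = float(min(mean_loss.index[mean_loss == mean_loss.min()]))

    scaler = StandardScaler().fit(x_all)
    model = _make_model(spec.model_kind, best, spec.seed)
    model.fit(scaler.transform(x_all), y_all)

    coefficients = _destandardize(spec, scaler, model)
    coef_se = _ols_standard_errors(spec, x_all, y_all) if spec.model_kind == "linear" else None
    return FitResult(spec=spec, scaler=scaler, model=model, best_strength=best,
                     cv_summary=cv_summary, coefficients=coefficients, coef_se=coef_se)


def _destandardize(spec: ModelSpec, scaler: StandardScaler, model) -> dict:
    """Map fitted coefficients from the z-scored scale back to mm units."""
    scale = scaler.scale_
    mean = scaler.mean_
    if spec.model_kind == "linear":
        beta = model.coef_ / scale
        intercept = float(model.intercept_ - np.sum(model.coef_ * mean / scale))
        out = {"intercept": intercept}
        out.update({f: float(b) for f, b in zip(spec.features, beta)})
        return out
    out = {}
    for cls, coef, icpt in zip(model.classes_, model.coef_, model.intercept_):
        beta = coef / scale
        out[str(cls)] = {
            "intercept": float(icpt - np.sum(coef * mean / scale)),
            **{f: float(b) for f, b in zip(spec.features, beta)},
        }
    return out


def _ols_standard_errors(spec: ModelSpec, x: np.ndarray, y: np.ndarray) -> dict:
    """Classical OLS coefficient standard errors on the original scale."""
    n, p = x.shape
    xd = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(xd, y.astype(float), rcond=None)
    resid = y.astype(float) - xd @ beta
    dof = n - p - 1
    if dof <= 0:
        return {}
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(xd.T @ xd)
    se = np.sqrt(np.diag(cov))
    out = {"intercept": float(se[0])}
    out.update({f: float(s) for f, s in zip(spec.features, se[1:])})
    return out


def predict_growth(fit: FitResult, frame: pd.DataFrame) -> np.ndarray:
    """Predicted annual growth (mm/yr) from a fitted linear model."""
    if fit.spec.model_kind != "linear":
        raise ValueError("predict_growth needs a linear model fit")
    x = design_matrix(frame, fit.spec.features)
    return fit.model.predict(fit.scaler.transform(x))


def class_probability(fit: FitResult, frame: pd.DataFrame, which: str) -> np.ndarray:
    """Predicted probability of one growth category from the logistic fit."""
    if fit.spec.model_kind != "multinomial_logistic":
        raise ValueError("class probabilities need a multinomial logistic fit")
    if which not in CATEGORIES:
        raise ValueError(f"unknown category {which!r}")
    x = design_matrix(frame, fit.spec.features)
    proba = fit.model.predict_proba(fit.scaler.transform(x))
    classes = list(fit.model.classes_)
    if which not in classes:
        raise SingleClassError(f"class {which!r} absent from the training data")
    return proba[:, classes.index(which)]


def roc_at_threshold(fit: FitResult, test: pd.DataFrame,
                     which: str) -> tuple[pd.DataFrame, float]:
    """One-vs-rest ROC curve and trapezoidal AUROC for one growth category."""
    if len(test) == 0:
        raise ValueError("empty test set")
    score = class_probability(fit, test, which)
    y = (test["category"].to_numpy() == which).astype(int)
    if y.min() == y.max():
        raise SingleClassError(
            f"test set has a single class for the {which!r} binarization")
    fpr, tpr, thr = roc_curve(y, score)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(auc(fpr, tpr))


def auroc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the rank-statistic identity U / (n1 * n0), tie-corrected.

    Provided as the independent cross-check of the trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise SingleClassError("need both classes for AUROC")
    ranks = stats.rankdata(scores)
    u = float(ranks[labels].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def compare_auroc(fit_a: FitResult, fit_b: FitResult, test: pd.DataFrame,
                  which: str, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Paired bootstrap test for an AUROC difference on a shared test set.

    Returns ``(delta, p)`` where ``delta = AUROC_a - AUROC_b`` on the full
    test set and ``p`` is the two-sided bootstrap p-value over ``n_boot``
    row resamples.  Two identical score vectors give delta 0 and p ~ 1.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    score_a = class_probability(fit_a, test, which)
    score_b = class_probability(fit_b, test, which)
    y = (test["category"].to_numpy() == which).astype(int)
    if y.min() == y.max():
        raise SingleClassError(
            f"test set has a single class for the {which!r} binarization")
    delta = auroc_mann_whitney(score_a, y) - auroc_mann_whitney(score_b, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    deltas = np.empty(n_boot)
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue  # resample lost a class; draw again
        deltas[i] = auroc_mann_whitney(score_a[idx], y[idx]) - \
            auroc_mann_whitney(score_b[idx], y[idx])
        i += 1
    lo = (1 + np.sum(deltas <= 0)) / (n_boot + 1)
    hi = (1 + np.sum(deltas >= 0)) / (n_boot + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return float(delta), float(p)


def evaluate_linear(fit: FitResult, test: pd.DataFrame, margin: float = 2.0) -> dict:
    """Test-set metrics of a linear growth model.

    RMSE (mm/yr), Pearson and Spearman correlations of predicted vs
    observed growth, and the fraction of predictions whose absolute error
    is within ``margin`` mm/yr (boundary inclusive; 2 mm is the accepted
    technical variability of APD measurement on CT).
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = predict_growth(fit, test)
    obs = test["annual_growth_mm_yr"].to_numpy(dtype=float)
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        pearson = spearman_r = math.nan
    else:
        pearson = float(stats.pearsonr(pred, obs).statistic)
        spearman_r = float(stats.spearmanr(pred, obs).statistic)
    within = float(np.mean(np.abs(err) <= margin))
    return {
        "rmse_mm": rmse,
        "pearson_r": pearson,
        "spearman_r": spearman_r,
        "within_2mm_fraction": within,
        "mae_mm": float(np.mean(np.abs(err))),
        "n_test": int(len(test)),
    }
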