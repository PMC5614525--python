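"""Personal and population predictive models under leave-one-out CV.

Binary families: L2-penalized logistic regression, RBF-kernel SVM, random
forest (plus a constant dummy for testing).  Regression families:
elastic-net and lasso linear regression.  Outer evaluation is leave-one-out;
hyperparameters come from an inner 10-fold grid search, by default nested
inside every outer training set (``hyper_mode="nested"``) with a faster
``"once"`` mode that selects them a single time on the full training scope.
Features are standardized with training-fold statistics only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet, Lasso, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .baselines import BINARY, REGRESSION, prediction_error, rmse
from .exceptions import ContractError
from .mobility import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

#: tie-break order for family selection (simpler first)
FAMILY_ORDER = {
    BINARY: ["constant", "logreg", "svm_rbf", "random_forest"],
    REGRESSION: ["constant", "lasso", "elastic_net"],
}

DEFAULT_GRIDS = {
    "logreg": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "random_forest": {"n_estimators": [100], "max_depth": [None, 3]},
    "elastic_net": {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.1, 0.5, 0.9]},
    "lasso": {"alpha": [0.01, 0.1, 1.0]},
    "constant": {},
}


@dataclass(frozen=True)
class ModelSpec:
    """One (task, family) evaluation recipe."""

    task: str
    family: str
    grid: dict = None
    inner_folds: int = 10
    seed: int = 0
    hyper_mode: str = "nested"  # "nested" | "once"
    clip_to_scale: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family not in FAMILY_ORDER[self.task]:
            raise ContractError(f"family {self.family!r} invalid for task {self.task!r}")
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])
        if self.family != "constant" and self.grid is not None and len(self.grid) == 0:
            raise ContractError("hyperparameter grid must be non-empty")
        if self.hyper_mode not in ("nested", "once"):
            raise ContractError("hyper_mode must be 'nested' or 'once'")


@dataclass
class ModelEvalResult:
    user_id: str
    scope: str  # personal | population
    task: str
    family: str
    error: float
    n_evaluations: int
    n_fallbacks: int = 0
    params: dict = field(default_factory=dict)


class _ConstantModel:
    """Mode / mean predictor; also the single-class fallback for classifiers."""

    def __init__(self, task):
        self.task = task

    def fit(self, X, y):
        if self.task == BINARY:
            pos = int(np.sum(y))
            self.value_ = 1 if pos > len(y) - pos else 0
        else:
            self.value_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.value_)


def _make_estimator(spec: ModelSpec, params: dict):
    if spec.family == "logreg":
        # liblinear: L2 penalty by default, fastest solver at LOOCV problem sizes
        return LogisticRegression(max_iter=2000, solver="liblinear", **params)
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", **params)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.family == "elastic_net":
        return ElasticNet(max_iter=5000, **params)
    if spec.family == "lasso":
        return Lasso(max_iter=5000, **params)
    if spec.family == "constant":
        return _ConstantModel(spec.task)
    raise ContractError(f"unknown family {spec.family!r}")


def _standardize(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _fit_predict(spec: ModelSpec, params: dict, Xtr, ytr, Xte):
    """Fit one estimator on (Xtr, ytr) and predict Xte; returns (preds, used_fallback)."""
    fallback = False
    if spec.task == BINARY and len(np.unique(ytr)) < 2:
        est = _ConstantModel(BINARY)
        fallback = True
    else:
        est = _make_estimator(spec, params)
    Xtr_s, Xte_s = _standardize(Xtr, Xte)
    est.fit(Xtr_s, ytr)
    preds = est.predict(Xte_s)
    if spec.task == REGRESSION and spec.clip_to_scale is not None:
        preds = np.clip(preds, *spec.clip_to_scale)
    return preds, fallback


def _grid_points(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def _error(spec: ModelSpec, preds, true) -> float:
    if spec.task == BINARY:
        return prediction_error(np.asarray(preds).astype(int), np.asarray(true).astype(int))
    return rmse(preds, true)


def select_hyperparameters(spec: ModelSpec, X, y) -> dict:
    """Inner k-fold grid search; ties keep the first grid point."""
    points = _grid_points(spec.grid)
    if len(points) == 1:
        return points[0]
    n_splits = min(spec.inner_folds, len(y))
    if n_splits < 2:
        return points[0]
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(X))
    best, best_err = points[0], np.inf
    for params in points:
        preds = np.empty(len(y), dtype=float)
        for tr, te in folds:
            preds[te], _ = _fit_predict(spec, params, X[tr], y[tr], X[te])
        err = _error(spec, preds, y)
        if err < best_err - 1e-12:
            best, best_err = params, err
    return best


def _loocv(spec: ModelSpec, X: np.ndarray, y: np.ndarray, audit: list | None = None
           ) -> tuple[np.ndarray, int, dict]:
    """Leave-one-out predictions over (X, y); returns (preds, n_fallbacks, params)."""
    n = len(y)
    preds = np.empty(n, dtype=float)
    n_fallbacks = 0
    params = {}
    if spec.hyper_mode == "once":
        params = select_hyperparameters(spec, X, y)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        if audit is not None:
            audit.append(tr.copy())
        p = params if spec.hyper_mode == "once" else \
            select_hyperparameters(spec, X[tr], y[tr])
        pred_i, fb = _fit_predict(spec, p, X[tr], y[tr], X[[i]])
        preds[i] = pred_i[0]
        n_fallbacks += int(fb)
    return preds, n_fallbacks, params


def _design(day_records: pd.DataFrame, task: str) -> tuple[np.ndarray, np.ndarray]:
    X = day_records[FEATURE_COLUMNS].to_numpy(dtype=float)
    col = "label_binary" if task == BINARY else "label_level"
    y = day_records[col].to_numpy()
    return X, (y.astype(int) if task == BINARY else y.astype(float))


def loocv_personal(user_days: pd.DataFrame, spec: ModelSpec,
                   audit: list | None = None) -> ModelEvalResult:
    """Leave-one-out error of a model trained only on this user's other days."""
    users = user_days["user_id"].unique()
    if len(users) != 1:
        raise ContractError("loocv_personal expects a single user's rows")
    min_days = max(spec.inner_folds + 1, 10)
    if len(user_days) < min_days:
        raise ContractError(f"user {users[0]} has {len(user_days)} days; "
                            f"needs >= {min_days} for nested LOOCV")
    X, y = _design(user_days, spec.task)
    preds, n_fallbacks, params = _loocv(spec, X, y, audit)
    if n_fallbacks:
        logger.info("user %s: %d single-class folds fell back to a constant predictor",
                    users[0], n_fallbacks)
    return ModelEvalResult(user_id=str(users[0]), scope="personal", task=spec.task,
                           family=spec.family, error=_error(spec, preds, y),
                           n_evaluations=len(y), n_fallbacks=n_fallbacks, params=params)


def loocv_population(day_records: pd.DataFrame, spec: ModelSpec,
                     audit: list | None = None
                     ) -> tuple[float, list[ModelEvalResult]]:
    """Pooled leave-one-out over all users' days; per-user errors from held-out rows.

    Returns (pooled error over every prediction, per-user results).  Some of
    each user's data is seen in training for every other row — that is the
    defining property of a population model.
    """
    if day_records["user_id"].nunique() < 1:
        raise ContractError("loocv_population requires at least one user")
    recs = day_records.sort_values(["user_id", "date"], kind="mergesort").reset_index(drop=True)
    X, y = _design(recs, spec.task)
    preds, n_fallbacks, _ = _loocv(spec, X, y, audit)
    pooled = _error(spec, preds, y)
    out = []
    for user_id, rows in recs.groupby("user_id", sort=True):
        idx = rows.index.to_numpy()
        out.append(ModelEvalResult(
            user_id=str(user_id), scope="population", task=spec.task, family=spec.family,
            error=_error(spec, preds[idx], y[idx]), n_evaluations=len(idx)))
    return pooled, out


def select_best_family(mean_errors: dict[str, float], task: str) -> str:
    """Family with the lowest average error; ties go to the earlier entry in
    the documented order (simpler families first)."""
    if not mean_errors:
        raise ContractError("no families evaluated")
    order = {f: i for i, f in enumerate(FAMILY_ORDER[task])}
    return min(mean_errors, key=lambda f: (mean_errors[f], order.get(f, len(order))))


def model_eval_table(results: list[ModelEvalResult]) -> pd.DataFrame:
    """model_eval.csv content."""
    return pd.DataFrame([{
        "user_id": r.user_id, "scope": r.scope, "task": r.task, "family": r.family,
        "error": r.error, "n_evaluations": r.n_evaluations, "n_fallbacks": r.n_fallbacks,
    } for r in results])
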