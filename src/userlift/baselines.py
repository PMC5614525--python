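"""Constant-guess baselines and their error metrics.

A *personal* baseline always guesses a user's own most frequent binary state
(mode) or mean level; a *population* baseline guesses the pooled cohort's
mode or mean for everyone.  Binary error is percent incorrect; level error
is RMSE in Likert units.  Among constant predictors the mode minimizes 0-1
loss and the mean minimizes RMSE, so the personal baseline can never do
worse than the population baseline on any user.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ContractError

POPULATION = "__population__"

BINARY = "binary"
REGRESSION = "regression"


@dataclass(frozen=True)
class BaselineResult:
    user_id: str  # POPULATION sentinel for the pooled result
    task: str
    constant_prediction: float
    error: float  # percent incorrect (binary) or RMSE (regression)


def prediction_error(predicted, true) -> float:
    """Percent of observations incorrectly predicted."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ContractError("predicted and true must be equal-length, non-empty")
    return 100.0 * float(np.mean(predicted != true))


def rmse(predicted, true) -> float:
    """Root mean squared error."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ContractError("predicted and true must be equal-length, non-empty")
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


def _mode_negative_ties(binary_labels: np.ndarray) -> int:
    """Most frequent binary label; ties go to the negative class (0)."""
    pos = int(np.sum(binary_labels))
    neg = binary_labels.size - pos
    return 1 if pos > neg else 0


def _constant_and_error(labels: np.ndarray, task: str) -> tuple[float, float]:
    if task == BINARY:
        const = _mode_negative_ties(labels.astype(int))
        return float(const), prediction_error(np.full(labels.shape, const), labels.astype(int))
    if task == REGRESSION:
        const = float(np.mean(labels))
        return const, rmse(np.full(labels.shape, const), labels)
    raise ContractError(f"unknown task {task!r}")


def _labels(day_records: pd.DataFrame, task: str) -> np.ndarray:
    col = "label_binary" if task == BINARY else "label_level"
    return day_records[col].to_numpy()


def personal_baseline(user_days: pd.DataFrame, task: str) -> BaselineResult:
    """Constant guess from a user's own qualifying days, evaluated on those days."""
    if len(user_days) == 0:
        raise ContractError("personal_baseline requires at least one qualifying day")
    users = user_days["user_id"].unique()
    if len(users) != 1:
        raise ContractError("personal_baseline expects a single user's rows")
    labels = _labels(user_days, task)
    const, err = _constant_and_error(labels, task)
    return BaselineResult(user_id=str(users[0]), task=task,
                          constant_prediction=const, error=err)


def population_baseline(day_records: pd.DataFrame, task: str
                        ) -> tuple[BaselineResult, list[BaselineResult]]:
    """One pooled constant for everybody, plus its per-user error breakdown."""
    if len(day_records) == 0:
        raise ContractError("population_baseline requires at least one day record")
    labels = _labels(day_records, task)
    const, pooled_err = _constant_and_error(labels, task)
    pooled = BaselineResult(user_id=POPULATION, task=task,
                            constant_prediction=const, error=pooled_err)
    per_user = []
    for user_id, rows in day_records.groupby("user_id", sort=True):
        ul = _labels(rows, task)
        if task == BINARY:
            err = prediction_error(np.full(ul.shape, int(const)), ul.astype(int))
        else:
            err = rmse(np.full(ul.shape, const, dtype=float), ul)
        per_user.append(BaselineResult(user_id=str(user_id), task=task,
                                       constant_prediction=const, error=err))
    return pooled, per_user


def personal_baselines(day_records: pd.DataFrame, task: str) -> list[BaselineResult]:
    """Personal baseline for every user in a qualifying-day table."""
    return [personal_baseline(rows, task)
            for _, rows in day_records.groupby("user_id", sort=True)]


def loocv_personal_baseline(user_days: pd.DataFrame, task: str) -> BaselineResult:
    """Leave-one-out variant: each day is guessed from the user's other days.

    Off by default in the pipeline; provided for strict comparability with
    leave-one-out model errors.
    """
    if len(user_days) < 2:
        raise ContractError("loocv baseline requires >= 2 qualifying days")
    users = user_days["user_id"].unique()
    if len(users) != 1:
        raise ContractError("loocv_personal_baseline expects a single user's rows")
    labels = _labels(user_days, task)
    preds = np.empty(labels.shape, dtype=float)
    for i in range(labels.size):
        rest = np.delete(labels, i)
        if task == BINARY:
            preds[i] = _mode_negative_ties(rest.astype(int))
        else:
            preds[i] = float(np.mean(rest))
    if task == BINARY:
        err = prediction_error(preds.astype(int), labels.astype(int))
    else:
        err = rmse(preds, labels)
    return BaselineResult(user_id=str(users[0]), task=task,
                          constant_prediction=float("nan"), error=err)


def baselines_table(day_records: pd.DataFrame, tasks=(BINARY, REGRESSION)) -> pd.DataFrame:
    """baselines.csv content: personal and population constants and errors."""
    rows = []
    for task in tasks:
        for r in personal_baselines(day_records, task):
            rows.append({"user_id": r.user_id, "scope": "personal", "task": task,
                         "constant": r.constant_prediction, "error": r.error})
        pooled, per_user = population_baseline(day_records, task)
        rows.append({"user_id": pooled.user_id, "scope": "population", "task": task,
                     "constant": pooled.constant_prediction, "error": pooled.error})
        for r in per_user:
            rows.append({"user_id": r.user_id, "scope": "population_per_user", "task": task,
                         "constant": r.constant_prediction, "error": r.error})
    return pd.DataFrame(rows)
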