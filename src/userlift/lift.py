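"""User lift and the one-sample sign-flip permutation test.

*User lift* for one user is ``personal baseline error − model error`` (in
percent-incorrect or RMSE units): it measures how much an algorithm improves
on the trivial guess that the user is always at their own most frequent /
average state.  Positive lift means the model adds information; a cohort of
lifts near zero means the model is, for practical purposes, reproducing the
personal baseline.

Whether the cohort's *mean* lift exceeds zero is tested with a one-sample
sign-flip permutation test: under the null hypothesis each user's lift is
symmetric about zero, so its sign is exchangeable.  With n users there are
2^n equally likely sign patterns; the p-value is the fraction of patterns
whose mean is at least the observed mean.  Up to n = 20 the test enumerates
all patterns exactly (meet-in-the-middle, so n = 20 costs a 1024x1024 outer
sum); larger cohorts use seeded Monte Carlo with the standard +1 correction.

The module follows the statsmodels convention: build a :class:`UserLiftTest`
from per-user errors or lifts, call :meth:`~UserLiftTest.fit`, and read the
:class:`UserLiftResults` (estimates, p-value, descriptives, ``summary()``,
``plot()``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ContractError

#: cohorts up to this size are tested by exact enumeration of 2^n sign patterns
EXACT_ENUMERATION_CAP = 20

_TIE_EPS = 1e-9


def user_lift(personal_baseline_error: float, personal_model_error: float) -> float:
    """Baseline error minus model error; positive = the model beats the baseline.

    Both arguments must be in the same units (both percent incorrect or both
    RMSE) and non-negative.
    """
    b = float(personal_baseline_error)
    m = float(personal_model_error)
    if b < 0 or m < 0:
        raise ContractError("errors must be non-negative and in the same metric")
    return b - m


def mean_lift_and_descriptives(lifts) -> dict[str, float]:
    """Mean, quartiles and 5th/95th percentiles of a lift sample.

    Percentiles use linear interpolation between order statistics (the numpy
    default).
    """
    lifts = np.asarray(lifts, dtype=float)
    if lifts.size == 0:
        raise ContractError("need at least one lift")
    q5, q25, q50, q75, q95 = np.percentile(lifts, [5, 25, 50, 75, 95])
    return {"mean": float(lifts.mean()), "p5": float(q5), "q1": float(q25),
            "median": float(q50), "q3": float(q75), "p95": float(q95)}


@dataclass
class PermTestResult:
    """Outcome of the sign-flip test with its resampling provenance."""

    mean_lift: float
    p_value: float
    method: str  # "exact" | "monte_carlo"
    n_permutations: int
    seed: int | None
    per_user_lifts: np.ndarray = field(repr=False, default=None)


def _exact_p(lifts: np.ndarray) -> tuple[float, int]:
    """P(sign-flipped sum >= observed sum) by meet-in-the-middle enumeration."""
    n = lifts.size
    half = n // 2
    a, b = lifts[:half], lifts[half:]

    def all_sums(v):
        s = np.zeros(1)
        for x in v:
            s = np.concatenate([s - x, s + x])
        return s

    sa, sb = all_sums(a), all_sums(b)
    observed = lifts.sum()
    thresh = observed - _TIE_EPS * (1.0 + abs(observed))
    sb_sorted = np.sort(sb)
    # for each half-sum in sa, count sb entries with sa + sb >= thresh
    count = int(np.sum(len(sb_sorted) - np.searchsorted(sb_sorted, thresh - sa, side="left")))
    total = 2 ** n
    return count / total, total


def permutation_test_mean_gt_zero(lifts, n_permutations: int = 10_000,
                                  seed: int | None = None) -> PermTestResult:
    """One-sided test of mean(lifts) > 0 under the sign-symmetry null.

    Exact for n <= 20 (p = #{sign patterns with mean >= observed} / 2^n);
    Monte Carlo otherwise with p = (1 + #{resampled >= observed}) / (1 + B).
    """
    lifts = np.asarray(lifts, dtype=float)
    if lifts.size < 2:
        raise ContractError("permutation test requires at least 2 lifts")
    observed = float(lifts.mean())
    if lifts.size <= EXACT_ENUMERATION_CAP:
        p, total = _exact_p(lifts)
        return PermTestResult(mean_lift=observed, p_value=p, method="exact",
                              n_permutations=total, seed=seed, per_user_lifts=lifts)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, lifts.size)) * 2 - 1
    means = signs @ lifts / lifts.size
    thresh = observed - _TIE_EPS * (1.0 + abs(observed))
    hits = int(np.sum(means >= thresh))
    p = (1 + hits) / (1 + n_permutations)
    return PermTestResult(mean_lift=observed, p_value=p, method="monte_carlo",
                          n_permutations=n_permutations, seed=seed, per_user_lifts=lifts)


def monte_carlo_permutation_test(lifts, n_permutations: int = 10_000,
                                 seed: int | None = None) -> PermTestResult:
    """Monte-Carlo sign-flip test regardless of cohort size (for cross-checks)."""
    lifts = np.asarray(lifts, dtype=float)
    if lifts.size < 2:
        raise ContractError("permutation test requires at least 2 lifts")
    observed = float(lifts.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, lifts.size)) * 2 - 1
    means = signs @ lifts / lifts.size
    thresh = observed - _TIE_EPS * (1.0 + abs(observed))
    hits = int(np.sum(means >= thresh))
    return PermTestResult(mean_lift=observed, p_value=(1 + hits) / (1 + n_permutations),
                          method="monte_carlo", n_permutations=n_permutations,
                          seed=seed, per_user_lifts=lifts)


class UserLiftTest:
    """Model object for the user-lift evaluation of one (task, model) pair.

    Parameters
    ----------
    lifts : array-like
        Per-user lifts (baseline error − model error, one value per user).
    user_ids : sequence of str, optional
    metric : str
        Unit label for reporting ("percent" or "rmse").
    """

    def __init__(self, lifts, user_ids=None, metric: str = "percent"):
        self.lifts = np.asarray(lifts, dtype=float)
        if self.lifts.ndim != 1 or self.lifts.size == 0:
            raise ContractError("lifts must be a non-empty 1-D array")
        self.user_ids = list(user_ids) if user_ids is not None else \
            [f"user{i}" for i in range(self.lifts.size)]
        if len(self.user_ids) != self.lifts.size:
            raise ContractError("user_ids length must match lifts")
        self.metric = metric

    @classmethod
    def from_errors(cls, baseline_errors, model_errors, user_ids=None,
                    metric: str = "percent") -> "UserLiftTest":
        """Build from paired per-user personal-baseline and model errors."""
        b = np.asarray(baseline_errors, dtype=float)
        m = np.asarray(model_errors, dtype=float)
        if b.shape != m.shape:
            raise ContractError("baseline and model error vectors must align")
        lifts = np.array([user_lift(bi, mi) for bi, mi in zip(b, m)])
        return cls(lifts, user_ids=user_ids, metric=metric)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, baseline_col: str = "personal_baseline_error",
                       model_col: str = "personal_model_error",
                       user_col: str = "user_id", metric: str = "percent") -> "UserLiftTest":
        return cls.from_errors(df[baseline_col], df[model_col],
                               user_ids=df[user_col].tolist(), metric=metric)

    def fit(self, n_permutations: int = 10_000, seed: int | None = None) -> "UserLiftResults":
        """Run the sign-flip test (exact when n <= 20) and package the results."""
        test = permutation_test_mean_gt_zero(self.lifts, n_permutations=n_permutations,
                                             seed=seed)
        return UserLiftResults(model=self, test=test,
                               descriptives=mean_lift_and_descriptives(self.lifts))


class UserLiftResults:
    """Results of a fitted :class:`UserLiftTest`."""

    def __init__(self, model: UserLiftTest, test: PermTestResult, descriptives: dict):
        self.model = model
        self.test = test
        self.descriptives = descriptives

    @property
    def mean_lift(self) -> float:
        return self.test.mean_lift

    @property
    def p_value(self) -> float:
        return self.test.p_value

    @property
    def per_user_lifts(self) -> pd.Series:
        return pd.Series(self.model.lifts, index=self.model.user_ids, name="user_lift")

    def summary(self):
        """statsmodels-style text table of the lift distribution and test."""
        from statsmodels.iolib.table import SimpleTable

        d = self.descriptives
        unit = "%" if self.model.metric == "percent" else "RMSE units"
        rows = [
            ["n users", f"{self.model.lifts.size}"],
            [f"mean lift ({unit})", f"{d['mean']:.4f}"],
            ["5th pct", f"{d['p5']:.4f}"],
            ["1st quartile", f"{d['q1']:.4f}"],
            ["median", f"{d['median']:.4f}"],
            ["3rd quartile", f"{d['q3']:.4f}"],
            ["95th pct", f"{d['p95']:.4f}"],
            ["test", f"sign-flip ({self.test.method})"],
            ["n permutations", f"{self.test.n_permutations}"],
            ["P(mean lift > 0 by chance)", f"{self.p_value:.4f}"],
        ]
        return SimpleTable(rows, headers=["", "user lift"],
                           title="User-lift permutation test")

    def plot(self, ax=None):
        """Box-style display: box = quartiles, whiskers = 5th/95th pct, line = mean."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3, 4))
        d = self.descriptives
        ax.add_patch(plt.Rectangle((0.75, d["q1"]), 0.5, d["q3"] - d["q1"],
                                   fill=False, edgecolor="k"))
        ax.plot([1, 1], [d["p5"], d["q1"]], "k-")
        ax.plot([1, 1], [d["q3"], d["p95"]], "k-")
        ax.plot([0.75, 1.25], [d["mean"], d["mean"]], "k-", lw=2)
        ax.axhline(0.0, color="grey", ls=":")
        ax.set_xlim(0.4, 1.6)
        ax.set_xticks([])
        ax.set_ylabel(f"user lift ({self.model.metric})")
        return ax


@dataclass
class CohortEvaluation:
    """Joined per-user errors, lifts, and permutation tests for one cohort."""

    eval_table: pd.DataFrame  # one row per user per (task, family)
    tests: dict[tuple[str, str], PermTestResult]
    summary_table: pd.DataFrame  # one row per (task, family)


def evaluate_cohort(baseline_errors: pd.DataFrame, model_errors: pd.DataFrame,
                    n_permutations: int = 10_000, seed: int | None = None,
                    dataset: str = "synthetic") -> CohortEvaluation:
    """Join per-user baseline and model errors, compute lifts, run the tests.

    ``baseline_errors`` needs columns user_id, task, error (personal scope,
    optionally population rows with scope column); ``model_errors`` needs
    user_id, task, family, error with scope == personal (population rows are
    carried through to the summary when present).  Users must match exactly
    between the personal rows of the two inputs for each task.
    """
    b = baseline_errors.copy()
    m = model_errors.copy()
    if "scope" not in b.columns:
        b["scope"] = "personal"
    if "scope" not in m.columns:
        m["scope"] = "personal"
    bp = b[b["scope"] == "personal"]
    mp = m[m["scope"] == "personal"]

    rows = []
    tests: dict[tuple[str, str], PermTestResult] = {}
    summary_rows = []
    for (task, family), grp in mp.groupby(["task", "family"], sort=True):
        base = bp[bp["task"] == task]
        bu, mu = set(base["user_id"]), set(grp["user_id"])
        if bu != mu:
            missing = sorted(bu.symmetric_difference(mu))
            raise ContractError(f"user sets differ between baselines and models "
                                f"for task {task!r}: {missing}")
        merged = base[["user_id", "error"]].rename(columns={"error": "personal_baseline_error"}) \
            .merge(grp[["user_id", "error"]].rename(columns={"error": "personal_model_error"}),
                   on="user_id").sort_values("user_id")
        merged["user_lift"] = merged["personal_baseline_error"] - merged["personal_model_error"]
        merged.insert(0, "task", task)
        merged.insert(1, "family", family)
        rows.append(merged)

        test = permutation_test_mean_gt_zero(merged["user_lift"].to_numpy(),
                                             n_permutations=n_permutations, seed=seed)
        tests[(task, family)] = test
        summary_rows.append({
            "dataset": dataset, "task": task, "model": family,
            "avg_personal_baseline_error": float(merged["personal_baseline_error"].mean()),
            "avg_model_error": float(merged["personal_model_error"].mean()),
            "avg_user_lift": test.mean_lift,
            "p_value": test.p_value,
        })

    return CohortEvaluation(eval_table=pd.concat(rows, ignore_index=True),
                            tests=tests, summary_table=pd.DataFrame(summary_rows))
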