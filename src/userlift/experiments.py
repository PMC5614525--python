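"""Repeated-cohort simulation batteries.

These drive the full pipeline over many independently seeded synthetic
cohorts to measure operating characteristics of the user-lift test: the
fraction of null cohorts declared significant (type-I behaviour end to end)
and the fraction of signal cohorts detected (power).  Batteries run at an
evaluation scale chosen for desk turnaround: 35 GPS fixes per day, the
cluster-count search capped at 6 (the generator plants 4 locations per
user), a single L2-logistic model family, and hyperparameters selected once
per training scope.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .lift import permutation_test_mean_gt_zero
from .mobility import fit_full_clustering
from .pipeline import PipelineSettings, default_model_specs, run_synthetic_pipeline
from .synthetic import CohortConfig

#: evaluation-scale cluster cap (generator plants 4 locations per user)
BATTERY_MAX_CLUSTERS = 6


def battery_config(effect_size: float, seed: int, n_users: int = 20,
                   n_days: int = 40) -> CohortConfig:
    """The study conditions used by the repeated-cohort batteries."""
    return CohortConfig(n_users=n_users, n_days=n_days, gps_obs_per_day=35,
                        effect_size=effect_size, seed=seed)


def battery_settings(seed: int, task: str = "binary") -> PipelineSettings:
    return PipelineSettings(
        max_clusters=BATTERY_MAX_CLUSTERS,
        gmm_n_init=1,
        seed=seed,
        model_specs=default_model_specs(tasks=(task,), hyper_mode="once", seed=seed),
    )


def run_lift_battery(n_cohorts: int = 50, effect_size: float = 0.0,
                     seed: int = 0, task: str = "binary",
                     n_users: int = 20, n_days: int = 40) -> pd.DataFrame:
    """Full pipeline on ``n_cohorts`` independent cohorts.

    Returns one row per cohort: mean user lift and permutation p-value for
    the requested task.  Cohort seeds are drawn from ``seed`` via a child
    spawn so cohorts are independent but reproducible.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_cohorts)]
    rows = []
    for i, cs in enumerate(cohort_seeds):
        config = battery_config(effect_size, cs, n_users=n_users, n_days=n_days)
        result = run_synthetic_pipeline(config, battery_settings(cs, task=task))
        summary = result.evaluation.summary_table.iloc[0]
        rows.append({"cohort": i, "seed": cs,
                     "mean_lift": float(summary["avg_user_lift"]),
                     "p_value": float(summary["p_value"]),
                     "avg_personal_baseline_error": float(summary["avg_personal_baseline_error"]),
                     "avg_model_error": float(summary["avg_model_error"])})
    return pd.DataFrame(rows)


def gmm_recovery_rate(n_sims: int = 20, seed: int = 0, separation: float = 6000.0,
                      noise_sd: float = 50.0, n_per_cluster: int = 70,
                      max_clusters: int = 20) -> float:
    """Fraction of simulations where BIC selection recovers 3 planted clusters.

    Cluster separation is far above the within-cluster spread, mimicking a
    user with three well-separated dwelling sites.
    """
    centers = np.array([[0.0, 0.0], [separation, 0.0], [0.0, separation]])
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(s)
        xy = np.vstack([rng.normal(c, noise_sd, size=(n_per_cluster, 2))
                        for c in centers])
        gmm = fit_full_clustering(xy, max_clusters=max_clusters, seed=s)
        hits += int(gmm.n_components == 3)
    return hits / n_sims


def type1_calibration(n_users: int = 20, n_replicates: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Rejection rate of the sign-flip test on i.i.d. standard-normal lifts.

    With exact enumeration the test is exact-level, so the rate should sit
    inside the binomial interval around alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        lifts = rng.standard_normal(n_users)
        res = permutation_test_mean_gt_zero(lifts)
        rejections += res.p_value <= alpha
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}
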