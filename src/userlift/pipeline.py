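"""End-to-end driver: simulate or load a cohort, featurize, evaluate lift.

`run_synthetic_pipeline` runs a generated cohort through the same stages the
CLI exposes on files — inclusion filters, daily labels, the two clusterings
and 14 daily features, constant baselines, leave-one-out model errors, and
the user-lift permutation test — entirely in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import baselines as bl
from . import ingest, mobility, modeling
from .lift import CohortEvaluation, evaluate_cohort
from .synthetic import CohortConfig, SimTruth, generate_cohort, scale_definition_dict


@dataclass
class PipelineSettings:
    """Stage parameters shared by the in-memory and file-based pipelines."""

    min_days: int = ingest.DEFAULT_MIN_DAYS
    min_gps_obs: int = ingest.DEFAULT_MIN_GPS_OBS
    max_clusters: int = mobility.MAX_CLUSTERS
    speed_threshold_kmh: float = mobility.STATIONARY_SPEED_KMH
    tz: str = "UTC"
    exclude_current_day: bool = False
    gmm_n_init: int = 2
    n_permutations: int = 10_000
    seed: int = 0
    model_specs: list[modeling.ModelSpec] = field(default_factory=list)
    include_population_models: bool = False


def default_model_specs(tasks=("binary",), hyper_mode: str = "nested",
                        seed: int = 0, families: dict | None = None
                        ) -> list[modeling.ModelSpec]:
    """One ModelSpec per requested (task, family)."""
    if families is None:
        families = {"binary": ["logreg"], "regression": ["elastic_net"]}
    return [modeling.ModelSpec(task=t, family=f, seed=seed, hyper_mode=hyper_mode)
            for t in tasks for f in families.get(t, [])]


@dataclass
class PipelineResult:
    day_records: pd.DataFrame
    features: pd.DataFrame
    cluster_models: dict
    baseline_table: pd.DataFrame
    model_results: list
    evaluation: CohortEvaluation
    truth: SimTruth | None = None


def featurize(locations: pd.DataFrame, responses: pd.DataFrame,
              scale: ingest.ScaleDefinition, settings: PipelineSettings
              ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Filters + labels + features; returns (qualifying day records with
    feature columns attached, features table, cluster models)."""
    days = ingest.build_day_records(responses, locations, scale, tz=settings.tz)
    days, retained = ingest.filter_participants(days, min_days=settings.min_days,
                                                min_gps_obs=settings.min_gps_obs)
    locations = locations[locations["user_id"].isin(retained)]
    features, models = mobility.extract_features(
        locations, days, max_clusters=settings.max_clusters,
        speed_threshold_kmh=settings.speed_threshold_kmh, tz=settings.tz,
        exclude_current_day=settings.exclude_current_day, seed=settings.seed,
        gmm_n_init=settings.gmm_n_init)
    merged = days.merge(features.drop(columns=["n_gps_obs"]),
                        on=["user_id", "date"], how="inner")
    return merged, features, models


def evaluate(day_features: pd.DataFrame, settings: PipelineSettings
             ) -> tuple[pd.DataFrame, list, CohortEvaluation]:
    """Baselines + LOOCV models + lift tests on a featurized day table."""
    tasks = sorted({s.task for s in settings.model_specs})
    baseline_table = bl.baselines_table(day_features, tasks=tasks)

    model_results = []
    for spec in settings.model_specs:
        for _, rows in day_features.groupby("user_id", sort=True):
            model_results.append(modeling.loocv_personal(rows, spec))
        if settings.include_population_models:
            _, per_user = modeling.loocv_population(day_features, spec)
            model_results.extend(per_user)

    b = baseline_table[baseline_table["scope"] == "personal"][["user_id", "task", "error"]]
    m = modeling.model_eval_table([r for r in model_results if r.scope == "personal"])
    evaluation = evaluate_cohort(b, m, n_permutations=settings.n_permutations,
                                 seed=settings.seed)
    return baseline_table, model_results, evaluation


def run_synthetic_pipeline(config: CohortConfig, settings: PipelineSettings
                           ) -> PipelineResult:
    """Generate a cohort and push it through featurization and evaluation."""
    if not settings.model_specs:
        settings.model_specs = default_model_specs(seed=settings.seed)
    locations, responses, truth = generate_cohort(config)
    scale = ingest.ScaleDefinition(**scale_definition_dict(config))
    day_features, features, models = featurize(locations, responses, scale, settings)
    baseline_table, model_results, evaluation = evaluate(day_features, settings)
    return PipelineResult(day_records=day_features, features=features,
                          cluster_models=models, baseline_table=baseline_table,
                          model_results=model_results, evaluation=evaluation,
                          truth=truth)
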