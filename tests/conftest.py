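import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from userlift.pipeline import PipelineSettings, default_model_specs, featurize
from userlift.synthetic import CohortConfig, generate_cohort, scale_definition_dict
from userlift.ingest import ScaleDefinition

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_users=4, n_days=30, gps_obs_per_day=35, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scale(small_config):
    return ScaleDefinition(**scale_definition_dict(small_config))


@pytest.fixture(scope="session")
def small_settings():
    return PipelineSettings(max_clusters=5, gmm_n_init=1, seed=11,
                            model_specs=default_model_specs(
                                tasks=("binary",), hyper_mode="once", seed=11))


@pytest.fixture(scope="session")
def small_day_features(small_cohort, small_scale, small_settings):
    """Featurized qualifying-day table for the 4-user cohort."""
    locations, responses, _ = small_cohort
    merged, features, models = featurize(locations, responses, small_scale,
                                         small_settings)
    return merged, features, models


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
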