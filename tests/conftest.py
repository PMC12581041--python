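import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from underdx import GeneratorConfig, generate_population, generate_survey

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete generator configuration."""
    return GeneratorConfig(
        n_survey=6000,
        disease_coefs={"intercept": -1.0, "age_group[80+]": 0.5, "sex[male]": 0.2},
        undiag_coefs={"intercept": -0.5, "sex[male]": 0.3, "year": -0.02},
        lsoas_per_ccg=2,
        pop_cell_mean=120.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    survey, truth = generate_survey(small_config, "diabetes")
    return survey, truth


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
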