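import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sigrev.signatures import build_signature, moderated_ttest
from sigrev.simulate import (
    SimulationConfig,
    generate_expression_cohort,
    generate_perturbation_library,
    generate_viability_screen,
    make_ground_truth,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def cohort_and_truth(default_config):
    return generate_expression_cohort(default_config)


@pytest.fixture(scope="session")
def truth(default_config):
    return make_ground_truth(default_config)[1]


@pytest.fixture(scope="session")
def signature(cohort_and_truth):
    matrix, _ = cohort_and_truth
    return build_signature(moderated_ttest(matrix), "synthetic_1")


@pytest.fixture(scope="session")
def library(default_config, truth):
    return generate_perturbation_library(default_config, truth)


@pytest.fixture(scope="session")
def screen(default_config, truth):
    return generate_viability_screen(default_config, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
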