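import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fecundmix import FitOptions, ParameterSet, hypothesis_suite
from fecundmix.published import WILCOX
from fecundmix.synthetic_data import SimConfig, simulate_study

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wilcox_params() -> ParameterSet:
    """The printed best-fit two-sub-cohort estimates of the 221-woman study."""
    return WILCOX.parameter_set()


@pytest.fixture(scope="session")
def sim_dataset_small(wilcox_params):
    """A moderate synthetic study (two-sub-cohort truth) for fitting tests."""
    config = SimConfig(
        n_initial=800,
        params=wilcox_params,
        n_cycles=7,
        dropout_prob=0.02,
        long_horizon=24,
        seed=11,
        study_name="sim-small",
    )
    dataset, _ = simulate_study(config)
    return dataset


@pytest.fixture(scope="session")
def suite_small(sim_dataset_small):
    """All five model fits plus the four nested tests, shared across tests."""
    return hypothesis_suite(sim_dataset_small, FitOptions(seed=2, n_starts=6))


@pytest.fixture(scope="session")
def fit0_small(suite_small):
    return suite_small.fits["0"]
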