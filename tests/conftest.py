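import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tripcheck import DosageCalibration, build_study
from tripcheck.pipeline import classify_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibration():
    return DosageCalibration()


@pytest.fixture(scope="session")
def exp1_cohort():
    """One default Experiment-1 style cohort shared across tests."""
    return build_study("experiment_1", seed=1)


@pytest.fixture(scope="session")
def exp1_classified(exp1_cohort):
    return classify_cohort(exp1_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
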