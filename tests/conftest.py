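import numpy as np
import pytest

from dcan.features import FeatureConfig
from dcan.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six patients, ~30 visits each: fast but structurally realistic."""
    cfg = SyntheticCohortConfig(n_patients=6, visits_per_patient=(28, 34), rng_seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_config():
    return SyntheticCohortConfig(n_patients=6, visits_per_patient=(28, 34), rng_seed=11)


@pytest.fixture()
def feature_config():
    return FeatureConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
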