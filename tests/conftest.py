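import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from retscat.config import OpticalConfig
from retscat.synthetic import CohortSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> OpticalConfig:
    """Default acquisition geometry (1 um lag pixel, 64 um max on-axis lag)."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_cfg() -> OpticalConfig:
    """Reduced angular sampling for cheap end-to-end runs."""
    return OpticalConfig(n_theta_x=64, n_theta_y=64)


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """A 3+3-eye, 4-location cohort with the default group effects."""
    return CohortSpec(n_wt_eyes=3, n_ad_eyes=3, n_locations=4, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
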