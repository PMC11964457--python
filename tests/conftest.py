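import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pdgait as pg

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects per class, 8 s walks — enough structure for plumbing tests."""
    return pg.simulate_cohort(pg.GaitSimConfig(n_subjects_per_class=3, duration=8.0, seed=3))


@pytest.fixture(scope="session")
def one_walk(small_cohort):
    return small_cohort.walks[0]
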