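import numpy as np
import pytest

import smcair


@pytest.fixture(scope="session")
def coarse_region():
    """Default-extent region at the fast 50 m test profile."""
    return smcair.generate_region(smcair.RegionConfig(cell_size=50.0, seed=7))


@pytest.fixture(scope="session")
def coarse_cohort(coarse_region):
    return smcair.generate_residences(coarse_region, smcair.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def factor_scores(coarse_region):
    return smcair.compute_factor_scores(coarse_region)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grid():
    return smcair.make_grid((0.0, 0.0, 1000.0, 800.0), 100.0)
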