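import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

from transrep.config import small_config
from transrep.pipeline import RunOptions, run_pipeline
from transrep.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced 3-population cohort with LD regions and chip missingness."""
    return simulate_cohort(small_config(seed=11, chip=True))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    """Full pipeline output on the small cohort."""
    return run_pipeline(cohort=small_cohort, opts=RunOptions(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
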