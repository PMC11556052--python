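import numpy as np
import pytest

from craniage.cohort import CohortConfig, sample_cohort
from craniage.pipeline import fixture_suite


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (n=223, default seed)."""
    return sample_cohort(CohortConfig())


@pytest.fixture(scope="session")
def mini_fixture():
    """Ten-subject mini cohort with rendered 48-cube volumes and features."""
    return fixture_suite(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
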