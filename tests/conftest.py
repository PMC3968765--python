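import numpy as np
import pytest

from ravensim.cohort import CohortSpec, calibrate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_321)


@pytest.fixture(scope="session")
def calibrated_spec():
    """Default behavioral-study cohort spec with loadings/difficulties solved."""
    return calibrate_cohort(CohortSpec())
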