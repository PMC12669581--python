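import numpy as np
import pytest

from protlca import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A study-condition three-class cohort used by the integration tests."""
    return generate_cohort(SimConfig(seed=13))


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged study-condition cohort (379 samples, 300 proteins)."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
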