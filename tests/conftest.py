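import numpy as np
import pytest

from glycofib.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort with its ground truth."""
    return generate_cohort(SyntheticConfig(), seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
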