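import numpy as np
import pytest

from ees_profile.synthetic import FixtureConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Default-geometry synthetic dataset (76 x 62, 5 informative)."""
    return generate_dataset(FixtureConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
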