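import numpy as np
import pytest

from mirdfuse import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30x25 planted-structure dataset shared by fast tests."""
    return generate_dataset(SyntheticSpec(p=30, q=25, rank=3, density=0.12, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
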