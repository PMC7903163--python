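import numpy as np
import pytest

from scmtf.synth import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Small model-generated dataset shared by read-only tests."""
    return generate_dataset(Is=80, Iv=12, Ig=8, Im=6, R=2, K=2, Q=1, seed=7)
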