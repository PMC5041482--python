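import numpy as np
import pytest

from codonmask import GeneratorConfig, make_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic study: 300/150/150 CLEAR/CUT/SUT-like ORFs."""
    return make_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick dataset for smoke/round-trip tests."""
    return make_dataset(GeneratorConfig(seed=3, n_clear=20, n_cut=10, n_sut=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
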