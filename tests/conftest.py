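import numpy as np
import pytest

from germqtl.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic experiment under the default (published-template)
    configuration; shared across tests that only read it."""
    return simulate_dataset(SimConfig(seed=20260929))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
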