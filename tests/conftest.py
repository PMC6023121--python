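import numpy as np
import pytest

from riparianpft import synthetic


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SyntheticDataset:
    """One default-condition synthetic study shared across tests."""
    return synthetic.generate_dataset(synthetic.SimConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
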