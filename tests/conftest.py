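import numpy as np
import pytest

from riverbio import synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """One deterministic synthetic dataset shared across tests."""
    config = synthetic.GeneratorConfig(seed=1)
    env, counts, truth = synthetic.generate_dataset(config)
    return config, env, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
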