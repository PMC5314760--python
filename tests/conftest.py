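import numpy as np
import pytest

from methnet import synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SyntheticConfig(n_genes=150, n_normal=20, n_tumor=20, seed=3)


@pytest.fixture(scope="session")
def small_net(small_config):
    return synth.generate_interactome(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_net):
    return synth.generate_cohort(small_config, small_net, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
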