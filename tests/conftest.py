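import numpy as np
import pytest

from optoephys import synthetic as syn


@pytest.fixture(scope="session")
def sim_config():
    return syn.SimConfig(seed=0, duration_s=120.0)


@pytest.fixture(scope="session")
def events(sim_config):
    return sim_config.events()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
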