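import numpy as np
import pytest

from mipqpi.synth import GeneratorConfig, make_phantom_cell


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=11, shape=(128, 128))


@pytest.fixture(scope="session")
def phantom(small_config):
    return make_phantom_cell(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
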