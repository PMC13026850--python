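import numpy as np
import pytest

import frozenseg as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest config the 3-stage topology admits: 16x16 canvas."""
    return fs.NetworkConfig.small(input_height=16, input_width=16)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return fs.build_network(tiny_config, seed=7)


@pytest.fixture(scope="session")
def small_scene_spec():
    return fs.SceneSpec.sinus_like(size=64)


@pytest.fixture(scope="session")
def overfit_pairs(small_scene_spec):
    """Eight 64x64 synthetic pairs used by the optimization sanity checks."""
    return [(p.image, p.mask) for p in fs.generate_dataset(small_scene_spec, 8, seed=42)]
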