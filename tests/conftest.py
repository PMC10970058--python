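import numpy as np
import pytest

from peggnet import nn
from peggnet.data import EggLabel, SyntheticEggParams, generate_synthetic_dataset


@pytest.fixture(autouse=True)
def _seed_layer_init():
    """Deterministic parameter init for every test."""
    nn.set_rng(1234)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_synthetic_set():
    """Four 64x64 images per class, rendered once per session."""
    params = SyntheticEggParams(image_size=64, seed=7)
    return generate_synthetic_dataset(params, {l: 4 for l in EggLabel})
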