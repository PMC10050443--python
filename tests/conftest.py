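import numpy as np
import pytest

from pvrnnlab.core import Architecture, LayerSpec, init_params
from pvrnnlab.environment import EnvConfig


@pytest.fixture
def env_cfg() -> EnvConfig:
    return EnvConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_arch() -> Architecture:
    """Small 2-layer network for gradient and dynamics checks."""
    return Architecture((LayerSpec(4, 2, 2.0), LayerSpec(3, 1, 5.0)))


@pytest.fixture
def tiny_params(tiny_arch, rng):
    return init_params(tiny_arch, rng)
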