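import numpy as np
import pytest

from snnpong.game import GameConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    return GameConfig()


@pytest.fixture
def small_config():
    """A 40x40 court (the desk-scale geometry)."""
    return GameConfig().scaled(4)
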