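import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def y_skeleton():
    """A Y: three straight arms meeting at one pixel."""
    skel = np.zeros((15, 15), dtype=np.uint8)
    for i in range(5):
        skel[7 + i + 1, 7] = 1          # stem straight down
        skel[7 - i - 1, 7 - i - 1] = 1  # upper-left arm
        skel[7 - i - 1, 7 + i + 1] = 1  # upper-right arm
    skel[7, 7] = 1
    return skel


@pytest.fixture
def small_system():
    """A modest synthetic root system plus truth, shared across tests."""
    from rootpcj import generate_root_system

    return generate_root_system(n_roots=4, rng_seed=7)
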