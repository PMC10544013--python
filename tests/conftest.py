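import numpy as np
import pytest

from wlc_apbc import ChainConformation, chain_from_angles


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def straight_chain():
    """N = 3 chain along +z with delta = 1."""
    beads = np.array([[0.0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]])
    return ChainConformation(beads=beads, delta=1.0)


@pytest.fixture
def kinked_chain():
    """Two segments meeting at a right angle: (0,0,1) then (1,0,0)."""
    beads = np.array([[0.0, 0, 0], [0, 0, 1], [1, 0, 1]])
    return ChainConformation(beads=beads, delta=1.0)


@pytest.fixture
def random_chain(rng):
    """A valid 20-segment chain with random joint angles."""
    n = 20
    polar = rng.uniform(0.0, np.pi * 0.95, size=n - 1)
    azim = rng.uniform(0.0, 2 * np.pi, size=n - 1)
    return chain_from_angles(polar, azim, delta=1.0)
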