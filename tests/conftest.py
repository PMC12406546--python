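import numpy as np
import pytest

from octex import BoundarySet, MVFImage, OCTVolume, PhantomConfig, generate_phantom
from octex.geometry import N_INTERFACES


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def flat_boundaries():
    """7 flat interfaces at depths 10, 20, ..., 70 on a 4x4 grid."""
    return BoundarySet(np.tile(np.arange(10.0, 80.0, 10.0)[:, None, None], (1, 4, 4)))


@pytest.fixture
def constant_volume():
    return OCTVolume(np.full((4, 4, 8), 7, dtype=np.uint8))


@pytest.fixture
def ramp_volume():
    """Volume whose intensity equals the axial depth index."""
    return OCTVolume(np.broadcast_to(np.arange(64.0), (4, 4, 64)).copy())


@pytest.fixture
def checkerboard_image():
    ch = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
    return MVFImage(values=ch, mask=np.ones_like(ch, bool), layer="IPL")


@pytest.fixture(scope="session")
def small_phantom():
    cfg = PhantomConfig(n_bscans=32, n_ascans=32, depth=256, seed=11)
    return generate_phantom(cfg)


def random_boundary_set(rng, nb=6, na=5, depth=200):
    """A random valid BoundarySet: sorted positive gaps below a margin."""
    hi = (depth - 8.0) / N_INTERFACES
    gaps = rng.uniform(1.0, hi, size=(N_INTERFACES, nb, na))
    depths = np.cumsum(gaps, axis=0) + rng.uniform(0, 4)
    assert depths.max() < depth
    return BoundarySet(depths)
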