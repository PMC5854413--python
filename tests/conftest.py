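import numpy as np
import pytest

from datquant.quantify import LabelAtlas
from datquant.synth import PhantomSpec, make_label_atlas, make_striatal_phantom
from datquant.volume import GridSpec, VolumeImage, default_grid


@pytest.fixture(scope="session")
def grid2() -> GridSpec:
    """The standard 2 mm normalized grid (91 x 109 x 91)."""
    return default_grid(2.0)


@pytest.fixture(scope="session")
def grid4() -> GridSpec:
    """A coarse 4 mm version of the standard grid for fast tests."""
    return default_grid(4.0)


@pytest.fixture(scope="session")
def atlas2(grid2) -> LabelAtlas:
    return make_label_atlas(grid2)


@pytest.fixture(scope="session")
def clean_phantom(grid2):
    """Noiseless, PSF-free default phantom plus its truth atlas."""
    return make_striatal_phantom(PhantomSpec(), grid2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_volume(shape=(12, 14, 10), voxel=2.0, seed=0, offset=(0.0, 0.0, 0.0)) -> VolumeImage:
    r = np.random.default_rng(seed)
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = offset
    return VolumeImage(r.uniform(0, 10, size=shape), aff, f"random-{seed}")
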