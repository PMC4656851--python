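"""Shared fixtures: small phantoms sized so the whole suite runs in minutes.

Fixtures are session-scoped where the underlying generators are pure
functions of their seeds, so repeated use is cheap and deterministic.
"""
import numpy as np
import pytest

from atlasforge.grids import VolumeGrid
from atlasforge.synthetic_data import (
    PhantomSpec,
    default_structures,
    make_line_panel,
    make_reference_brain,
)

# half-resolution grid of the default phantom: same physical brain, 8x fewer voxels
SMALL_SHAPE = (48, 80, 32)
SMALL_SPACING = (2.0, 2.0, 4.0)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING, seed=7)


@pytest.fixture(scope="session")
def brain_and_mask(small_spec):
    return make_reference_brain(small_spec)


@pytest.fixture(scope="session")
def brain(brain_and_mask) -> VolumeGrid:
    return brain_and_mask[0]


@pytest.fixture(scope="session")
def structures(small_spec):
    return default_structures(small_spec)


@pytest.fixture(scope="session")
def blob_panel(small_spec):
    """10 lines of planted rectangular footprints with exact ground truth."""
    return make_line_panel(10, {"kind": "random_blobs", "blobs_per_line": 2}, small_spec)


@pytest.fixture(scope="session")
def tiling_panel(small_spec):
    """4 lines that partition the brain mask into disjoint y-slabs."""
    return make_line_panel(4, {"kind": "tiling"}, small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)


def smooth_random_volume(shape, spacing, seed, lo=0.0, hi=1.0):
    """A smooth strictly-positive random field (helper, not a fixture)."""
    from scipy import ndimage

    r = np.random.default_rng(seed)
    data = ndimage.gaussian_filter(r.standard_normal(shape), sigma=2.0)
    data = (data - data.min()) / (data.max() - data.min())
    return VolumeGrid(lo + (hi - lo) * data, spacing)
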