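import numpy as np
import pytest

from scanqc.image import VoxelImage
from scanqc.simulate import PhantomSpec, make_phantom
from scanqc.snr import build_roi_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom():
    """Default 20 dB anatomical phantom."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture
def small_phantom():
    return make_phantom(PhantomSpec(dims=(48, 48, 16), seed=1))


def make_exact_snr_image(ratio: float, dims=(64, 64, 32)) -> VoxelImage:
    """Phantom with a known, exact sphere-mean / corner-std ratio.

    The signal is a uniform central ball of value ``ratio``; the corner
    cuboids carry a z-alternating 0/2 pattern whose population standard
    deviation is exactly 1 (each cuboid has an even z-extent, so the two
    values occur equally often).
    """
    vol = np.zeros(dims)
    center = tuple(d // 2 for d in dims)
    grids = np.ogrid[: dims[0], : dims[1], : dims[2]]
    ball = sum((g - c) ** 2 for g, c in zip(grids, center)) <= (min(dims) // 4) ** 2
    vol[ball] = ratio
    geom = build_roi_geometry(vol)
    zpattern = np.broadcast_to(
        2.0 * (np.arange(dims[2]) % 2), dims
    )
    vol = np.where(geom.cuboid_mask, zpattern, vol)
    return VoxelImage(vol)
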