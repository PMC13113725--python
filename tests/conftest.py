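import numpy as np
import pytest

from aortaquant.phantom import PhantomSpec, make_phantom
from aortaquant.volume_io import ImageVolume


@pytest.fixture(scope="session")
def straight_tube():
    """Straight tube along z: radius 15 mm, length 100 mm, 1 mm voxels."""
    spec = PhantomSpec(shape_kind="straight_tube", tube_radius_mm=15.0,
                       length_mm=100.0, spacing=(1.0, 1.0, 1.0))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def quarter_torus():
    """Quarter-torus tube: ring radius 50 mm, tube radius 10 mm."""
    spec = PhantomSpec(shape_kind="curved_tube", tube_radius_mm=10.0,
                       ring_radius_mm=50.0, spacing=(1.0, 1.0, 1.0))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def candy_cane():
    """Candy-cane phantom without stubs, 1 mm voxels (fast unit-test size)."""
    spec = PhantomSpec(shape_kind="candy_cane", tube_radius_mm=12.0,
                       ascending_mm=55.0, descending_mm=80.0,
                       ring_radius_mm=40.0, bulge=(30.0, 8.0, 10.0),
                       spacing=(1.0, 1.0, 1.0))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def candy_cane_stubs():
    """Candy cane with two branch stubs on the arch (landmark stand-ins)."""
    la, ring = 55.0, 40.0
    s_bct = la + 0.25 * np.pi * ring
    s_lsa = la + 0.75 * np.pi * ring
    spec = PhantomSpec(shape_kind="candy_cane", tube_radius_mm=12.0,
                       ascending_mm=la, descending_mm=80.0, ring_radius_mm=ring,
                       branch_stubs=((s_bct, 6.0, 30.0), (s_lsa, 6.0, 30.0)),
                       spacing=(1.0, 1.0, 1.0))
    return make_phantom(spec)


def make_ball_mask(radius_mm=10.0, spacing=(1.0, 1.0, 1.0), margin_mm=4.0):
    spacing = np.asarray(spacing, dtype=float)
    half = radius_mm + margin_mm
    shape = np.ceil(2 * half / spacing).astype(int) + 1
    center = (shape - 1) / 2.0 * spacing
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    return ImageVolume((d2 <= radius_mm ** 2).astype(np.uint8), spacing)


@pytest.fixture
def ball_mask():
    return make_ball_mask
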