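import numpy as np
import pytest

from phantomforge.volume_io import ImageVolume, SegmentationMask, Units


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """10^3 integer HU volume with 1 mm isotropic voxels."""
    data = rng.integers(-100, 200, size=(10, 10, 10)).astype(np.int32)
    return ImageVolume(data, (1.0, 1.0, 1.0), units=Units.HU)


@pytest.fixture
def cube_mask(small_volume):
    """Mask covering voxels (2..4)^3 of the small volume."""
    m = np.zeros(small_volume.shape, dtype=np.uint8)
    m[2:5, 2:5, 2:5] = 1
    return SegmentationMask(m, small_volume.spacing_mm, small_volume.origin_mm)


@pytest.fixture(scope="session")
def tiny_phantom():
    """A small digital phantom shared by the slower simulator tests."""
    from phantomforge.scansim import generate_digital_phantom

    return generate_digital_phantom(
        seed=11, n_lesions=2, extent_vox=(24, 72, 72), min_lesion_vox=6**3
    )


def lesion_crop(phantom, index):
    """Bounding-box crop of one lesion: (volume-box slices, cropped mask)."""
    m = phantom.lesion_masks[index].data > 0
    co = np.argwhere(m)
    lo, hi = co.min(axis=0), co.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    return box, m[box]
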