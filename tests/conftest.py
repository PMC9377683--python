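import numpy as np
import pytest

from otmorph import BlobSpec, DensityMap, blob_map, to_probability


@pytest.fixture(scope="session")
def two_blob_32():
    """Two identical σ=2 blobs 12 voxels apart on a 32³ grid."""
    a = blob_map((32, 32, 32), [BlobSpec((10, 16, 16), sigma=2.0)])
    b = blob_map((32, 32, 32), [BlobSpec((22, 16, 16), sigma=2.0)])
    return a, b


@pytest.fixture(scope="session")
def random_pair_6():
    """A seeded random pair of strictly positive 6³ measures."""
    rng = np.random.default_rng(20240917)
    p = to_probability(DensityMap(rng.random((6, 6, 6)) + 0.05))
    q = to_probability(DensityMap(rng.random((6, 6, 6)) + 0.05))
    return p, q


def centroid(data: np.ndarray) -> np.ndarray:
    """Intensity-weighted centre of a nonnegative field, in voxel coords."""
    idx = np.indices(data.shape)
    total = data.sum()
    return np.array([(idx[i] * data).sum() / total for i in range(3)])


def count_modes(data: np.ndarray, rel_height: float = 0.1) -> int:
    """Number of distinct local maxima above rel_height of the peak."""
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(data, 1.0)
    local_max = smooth == ndimage.maximum_filter(smooth, size=3)
    peaks = local_max & (smooth > rel_height * smooth.max())
    _, n = ndimage.label(peaks)
    return int(n)
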