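import numpy as np
import pytest

from asdnet.preprocessing import CTVolume, SliceSample
from asdnet.synthetic_data import PhantomSpec, desk_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_volume():
    """A hand-constructed 4-slice volume with known label placement."""
    voxels = np.full((4, 8, 8), 40.0, dtype=np.float32)
    labels = np.zeros((4, 8, 8), dtype=np.int16)
    labels[1, 2:5, 2:5] = 1          # kidney patch on slice 1
    labels[2, 3:6, 3:6] = 1          # kidney patch on slice 2 ...
    labels[2, 4, 4] = 2              # ... with a single tumor voxel
    voxels[1, 2:5, 2:5] = 120.0
    voxels[2, 3:6, 3:6] = 120.0
    voxels[2, 4, 4] = 70.0
    voxels[0, 0, 0] = -1000.0        # air voxel, outside the window
    voxels[3, 7, 7] = 700.0          # bone voxel, outside the window
    return CTVolume(voxels, labels, (3.0, 1.0, 1.0), "tiny")


@pytest.fixture
def square_sample(rng):
    img = rng.random((8, 8)).astype(np.float32)
    mask = (rng.random((8, 8)) > 0.7).astype(np.uint8)
    return SliceSample(img, mask, "case_x", 3, "kidney")


@pytest.fixture(scope="session")
def desk_phantom_spec():
    return desk_spec(seed=1)


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    """Smallest phantom that the depth-5 network accepts (48 = 16 * 3)."""
    return PhantomSpec(shape=(8, 48, 48), kidney_axes=((1.5, 2.5), (6, 9), (6, 9)),
                       tumor_radius=(2.0, 3.5), seed=2)
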