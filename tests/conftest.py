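import numpy as np
import pytest

from trabarch.volumes import VoxelVolume


@pytest.fixture(scope="session")
def balanced4_newick() -> str:
    return "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="session")
def crossed4_newick() -> str:
    return "((A:1,C:1):1,(B:1,D:1):1);"


@pytest.fixture(scope="session")
def ball_volume() -> VoxelVolume:
    """Digitised ball, radius 40 voxels, spacing 10 µm."""
    r = 40
    n = 2 * r + 5
    zz, yy, xx = np.indices((n, n, n))
    c = (n - 1) / 2
    data = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 < r * r
    return VoxelVolume(data, spacing=10.0)


def make_plate(size: int = 64, period: int = 10, thickness: int = 4,
               spacing: float = 20.0, axis: int = 0) -> VoxelVolume:
    idx = np.arange(size) % period < thickness
    shape = [1, 1, 1]
    shape[axis] = size
    data = np.zeros((size,) * 3, dtype=bool) | idx.reshape(shape)
    return VoxelVolume(data, spacing=spacing)


@pytest.fixture(scope="session")
def plate_volume() -> VoxelVolume:
    return make_plate()
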