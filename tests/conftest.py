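import numpy as np
import pytest

from voxelrxd.csg import build_csg
from voxelrxd.fixtures import make_cylinder, make_y
from voxelrxd.voxelize import GridParams, voxelize


@pytest.fixture(scope="session")
def y_grid():
    """The 30-degree Y geometry voxelized at the default resolution."""
    m = make_y()
    m.segmentize()
    return m, voxelize(build_csg(m), GridParams(dx=0.25))


@pytest.fixture(scope="session")
def small_cylinder_grid():
    """A 5x2 um cylinder at a generic (non-aligned) orientation."""
    m = make_cylinder(5.0, 2.0, (0.7, 1.1))
    m.segmentize()
    return m, voxelize(build_csg(m), GridParams(dx=0.25))


@pytest.fixture(scope="session")
def block_grid():
    """A fake 4x4x4 full-voxel grid for dense-oracle diffusion tests."""
    import types

    keys = np.array(
        [[i, j, k] for i in range(4) for j in range(4) for k in range(4)],
        dtype=np.int64,
    )
    dx = 0.5
    return types.SimpleNamespace(
        keys=keys, dx=dx, volumes=np.full(len(keys), dx ** 3)
    )
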