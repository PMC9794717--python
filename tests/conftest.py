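import numpy as np
import pytest

from mmlnm import GridSpec, TractSpec, make_lesion, make_tract_field


@pytest.fixture(scope="session")
def grid():
    return GridSpec((16, 16, 14), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def unit_grid():
    """Isotropic 1 mm grid where voxel and mm coordinates coincide."""
    return GridSpec((21, 11, 11), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def straight_tract_field(unit_grid):
    """A single straight +x tract through the grid center, radius 2 voxels."""
    tract = TractSpec(
        polyline=((0.0, 5.0, 5.0), (20.0, 5.0, 5.0)),
        radius=2.0,
        fa_inside=0.5,
        fa_outside=0.0,
    )
    dirs, fa = make_tract_field(unit_grid, [tract], seed=0)
    return dirs, fa, tract


@pytest.fixture(scope="session")
def small_lesion(grid):
    return make_lesion(grid, (8.0, 8.0, 7.0), 3.0)
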