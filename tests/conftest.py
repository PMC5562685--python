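import numpy as np
import pytest

from sbm import synthetic
from sbm.volume import VolumeGrid, default_grid


@pytest.fixture(scope="session")
def grid() -> VolumeGrid:
    """The default desk-scale analysis grid (24x28x24 @ 3 mm, ellipsoid mask)."""
    return default_grid()


@pytest.fixture(scope="session")
def small_grid() -> VolumeGrid:
    """A smaller grid for fast unit tests."""
    return default_grid(shape=(16, 18, 16), voxel_size_mm=(3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def box_grid() -> VolumeGrid:
    """A fully unmasked 12^3 grid at 1.5 mm for cluster-geometry tests."""
    shape = (12, 12, 12)
    affine = np.diag([1.5, 1.5, 1.5, 1.0])
    return VolumeGrid(shape=shape, voxel_size=(1.5, 1.5, 1.5), affine=affine,
                      mask=np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def synthetic_run(grid):
    """One shared synthetic cohort at the default study conditions."""
    gt = synthetic.make_ground_truth(grid, K=4, seed=5)
    cohort = synthetic.sample_cohort(synthetic.scaled_age_bins(150), seed=6)
    dm = synthetic.synthesize(gt, cohort)
    return gt, cohort, dm
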