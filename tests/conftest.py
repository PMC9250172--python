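import numpy as np
import pytest

from srseval import DoseGrid, StructureMask, VoxelGrid, sphere_mask


@pytest.fixture
def grid40():
    """1 mm isotropic 40 mm cube."""
    return VoxelGrid((40, 40, 40))


@pytest.fixture
def sphere5(grid40):
    """5 mm-radius sphere centered in the 40 mm grid."""
    return sphere_mask(grid40, (20.0, 20.0, 20.0), 5.0, name="PTV", role="PTV")


def step_dose(grid: VoxelGrid, mask: StructureMask, inside_Gy: float,
              outside_Gy: float = 0.0) -> DoseGrid:
    """Dose equal to inside_Gy on the mask, outside_Gy elsewhere."""
    dose = np.full(grid.shape, outside_Gy, dtype=float)
    dose[mask.voxels] = inside_Gy
    return DoseGrid(grid, dose)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
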