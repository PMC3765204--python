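import numpy as np
import pytest

from rpmap import PatientCase, VoxelGrid


@pytest.fixture
def grid16():
    return VoxelGrid.default((16, 16, 16))


@pytest.fixture
def case_factory():
    """Build a PatientCase from lists of tumor/residual voxel index triples."""

    def make(
        grid,
        case_id="p01",
        cohort="A",
        side="left",
        tumor_voxels=((1, 1, 1), (1, 1, 2)),
        residual_voxels=(),
    ):
        tumor = np.zeros(grid.shape, dtype=bool)
        residual = np.zeros(grid.shape, dtype=bool)
        for v in tumor_voxels:
            tumor[v] = True
        for v in residual_voxels:
            residual[v] = True
        return PatientCase(
            id=case_id, cohort=cohort, side=side, tumor=tumor, residual=residual, grid=grid
        )

    return make


def make_random_cases(grid, n, cohort="A", side="left", seed=0, p_resect=0.6):
    """Seeded random cohort of blocky masks on a small grid (same side)."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        tumor = np.zeros(grid.shape, dtype=bool)
        lo = rng.integers(0, np.asarray(grid.shape) - 4)
        size = rng.integers(3, 6, size=3)
        tumor[tuple(slice(a, min(a + s, dim)) for a, s, dim in zip(lo, size, grid.shape))] = True
        residual = tumor & (rng.random(grid.shape) >= p_resect)
        cases.append(
            PatientCase(
                id=f"{cohort}{i:02d}",
                cohort=cohort,
                side=side,
                tumor=tumor,
                residual=residual,
                grid=grid,
            )
        )
    return cases


@pytest.fixture
def random_cases():
    return make_random_cases
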