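import numpy as np
import pytest

from lesionmap import (
    HEMORRHAGIC,
    TOTAL,
    Cohort,
    LesionMask,
    SubjectRecord,
    VoxelGrid,
    make_default_atlas,
)


@pytest.fixture(scope="session")
def grid():
    return VoxelGrid.default()


@pytest.fixture(scope="session")
def atlas(grid):
    return make_default_atlas(grid)


def make_mask(grid, voxels, component=TOTAL):
    """Binary mask from a list of (i, j, k) index triples."""
    data = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        data[tuple(v)] = True
    return LesionMask(grid, component, data)


def make_subject(grid, sid, voxels, *, severity="severe", gcs=6, gose=5,
                 age=40.0, sex="male", pupils="normal", days_to_mri=7.0,
                 hem_voxels=None, **kw):
    masks = {TOTAL: make_mask(grid, voxels)}
    if hem_voxels is not None:
        masks[HEMORRHAGIC] = make_mask(grid, hem_voxels, HEMORRHAGIC)
    return SubjectRecord(
        id=sid, severity=severity, age=age, sex=sex, gcs=gcs, pupils=pupils,
        days_to_mri=days_to_mri, gose=gose, masks=masks, **kw,
    )


@pytest.fixture
def tiny_cohort(grid):
    """Five subjects with small hand-placed lesions inside the brain."""
    subs = [
        make_subject(grid, "a", [(12, 14, 12), (12, 15, 12)], severity="severe",
                     gcs=6, gose=3),
        make_subject(grid, "b", [(12, 14, 12)], severity="severe", gcs=7, gose=5),
        make_subject(grid, "c", [(11, 14, 12), (12, 14, 12)], severity="moderate",
                     gcs=12, gose=6),
        make_subject(grid, "d", [(10, 10, 10)], severity="moderate", gcs=11, gose=7),
        make_subject(grid, "e", [(13, 14, 12)], severity="severe", gcs=5, gose=8),
    ]
    return Cohort(grid, subs)
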