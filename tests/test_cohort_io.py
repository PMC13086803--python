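import numpy as np
import pandas as pd
import pytest

from lesionmap import (
    HEMORRHAGIC,
    TOTAL,
    Cohort,
    LesionMask,
    SubjectRecord,
    VoxelGrid,
    load_cohort,
    mask_volume_cm3,
    read_mask,
    save_cohort,
    tabulate_region_presence,
    write_mask,
)
from lesionmap.cohort_io import (
    DuplicateSubjectError,
    GridMismatchError,
    MaskReadError,
    SeverityGCSError,
    gose_to_category,
)

from conftest import make_mask, make_subject


class TestVoxelGrid:
    def test_default_geometry(self, grid):
        assert grid.shape == (24, 28, 24)
        assert np.allclose(grid.voxel_size_mm, 3.0)
        assert np.isclose(grid.voxel_volume_mm3, 27.0)

    def test_rejects_bad_shapes_and_affines(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 10, 10), np.eye(4))
        with pytest.raises(ValueError):
            VoxelGrid((10, 10, 10), np.zeros((4, 4)))

    def test_matches_tolerance(self, grid):
        aff = grid.affine.copy()
        aff[0, 3] += 5e-4
        assert grid.matches(VoxelGrid(grid.shape, aff))
        aff[0, 3] += 1.0
        assert not grid.matches(VoxelGrid(grid.shape, aff))


class TestMaskVolume:
    def test_empty_mask_is_zero(self, grid):
        assert mask_volume_cm3(make_mask(grid, [])) == 0.0

    @pytest.mark.parametrize(
        "n_voxels,voxel_size,expected",
        [(1000, 1.0, 1.0), (100, 3.0, 2.7), (1, 2.0, 0.008)],
    )
    def test_count_times_voxel_volume(self, n_voxels, voxel_size, expected):
        g = VoxelGrid.default((12, 12, 12), voxel_size)
        data = np.zeros(g.shape, dtype=bool)
        data.reshape(-1)[:n_voxels] = True
        assert np.isclose(LesionMask(g, TOTAL, data).volume_cm3, expected)

    def test_additive_over_disjoint_masks(self, grid):
        a = make_mask(grid, [(1, 1, 1), (2, 2, 2)])
        b = make_mask(grid, [(5, 5, 5)])
        both = make_mask(grid, [(1, 1, 1), (2, 2, 2), (5, 5, 5)])
        assert np.isclose(a.volume_cm3 + b.volume_cm3, both.volume_cm3)

    def test_invariant_under_axis_permutation(self):
        g1 = VoxelGrid.default((10, 12, 14), (1.0, 2.0, 3.0))
        g2 = VoxelGrid.default((14, 10, 12), (3.0, 1.0, 2.0))
        d = np.zeros(g1.shape, dtype=bool)
        d[1:4, 2:5, 3:6] = True
        m1 = LesionMask(g1, TOTAL, d)
        m2 = LesionMask(g2, TOTAL, np.transpose(d, (2, 0, 1)))
        assert np.isclose(m1.volume_cm3, m2.volume_cm3)


class TestMaskIO:
    def test_round_trip_preserves_voxels_and_affine(self, grid, tmp_path):
        rng = np.random.default_rng(0)
        m = LesionMask(grid, TOTAL, rng.random(grid.shape) > 0.7)
        path = tmp_path / "m.nii.gz"
        write_mask(m, path)
        back = read_mask(path, grid)
        assert np.array_equal(back.data, m.data)

    def test_shape_mismatch_names_file(self, tmp_path):
        g10 = VoxelGrid.default((10, 10, 10), 3.0)
        g12 = VoxelGrid.default((12, 12, 12), 3.0)
        path = tmp_path / "bad.nii.gz"
        write_mask(LesionMask(g10, TOTAL, np.zeros(g10.shape, dtype=bool)), path)
        with pytest.raises(MaskReadError, match="bad.nii.gz"):
            read_mask(path, g12)

    def test_probabilities_binarized_at_half(self, grid, tmp_path):
        import nibabel as nib

        data = np.zeros(grid.shape, dtype=np.float32)
        data[0, 0, 0] = 0.2
        data[1, 1, 1] = 0.7
        path = tmp_path / "p.nii.gz"
        nib.save(nib.Nifti1Image(data, grid.affine), str(path))
        m = read_mask(path, grid)
        assert not m.data[0, 0, 0] and m.data[1, 1, 1]

    def test_non_finite_rejected(self, grid, tmp_path):
        import nibabel as nib

        data = np.zeros(grid.shape, dtype=np.float32)
        data[2, 2, 2] = np.nan
        path = tmp_path / "nan.nii.gz"
        nib.save(nib.Nifti1Image(data, grid.affine), str(path))
        with pytest.raises(MaskReadError, match="non-finite"):
            read_mask(path, grid)


class TestSubjectRecord:
    @pytest.mark.parametrize(
        "gose,cat", [(1, 1), (4, 1), (5, 2), (6, 2), (7, 3), (8, 3), (None, None)]
    )
    def test_gose_category_rule(self, gose, cat):
        assert gose_to_category(gose) == cat

    def test_severity_gcs_contradiction(self, grid):
        with pytest.raises(SeverityGCSError):
            make_subject(grid, "x", [], severity="moderate", gcs=6)
        with pytest.raises(SeverityGCSError):
            make_subject(grid, "x", [], severity="severe", gcs=12)

    def test_gcs_above_13_rejected(self, grid):
        with pytest.raises(SeverityGCSError):
            make_subject(grid, "x", [], severity="moderate", gcs=14)

    def test_volumes_derived_from_masks(self, grid):
        s = make_subject(grid, "x", [(1, 1, 1), (2, 2, 2)], hem_voxels=[(1, 1, 1)])
        assert np.isclose(s.total_volume_cm3, 2 * 0.027)
        assert np.isclose(s.hemorrhagic_volume_cm3, 0.027)

    def test_component_inclusion_check(self, grid):
        inside = make_subject(grid, "x", [(1, 1, 1)], hem_voxels=[(1, 1, 1)])
        outside = make_subject(grid, "y", [(1, 1, 1)], hem_voxels=[(3, 3, 3)])
        assert inside.validate_component_inclusion()
        assert not outside.validate_component_inclusion()


class TestLoadCohort:
    def _write_manifest(self, tmp_path, grid, rows):
        mask_dir = tmp_path / "masks"
        mask_dir.mkdir(exist_ok=True)
        for r in rows:
            if r.get("mask_total"):
                m = make_mask(grid, [(int(r["id"][-1]), 5, 5)])
                write_mask(m, mask_dir / r["mask_total"])
        df = pd.DataFrame(rows)
        for col in ("gcs", "pupils", "gose", "tai_trondheim_grade",
                    "tai_standard_grade", "tai_volume_cm3", "mask_hemorrhagic"):
            if col not in df.columns:
                df[col] = None
        path = tmp_path / "manifest.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path, mask_dir

    def _row(self, sid, **kw):
        base = dict(id=sid, severity="severe", age=30, sex="male", gcs=6,
                    pupils="normal", days_to_mri=5, gose=6,
                    mask_total=f"{sid}.nii.gz")
        base.update(kw)
        return base

    def test_two_row_manifest(self, grid, tmp_path):
        path, md = self._write_manifest(tmp_path, grid, [self._row("s1"), self._row("s2")])
        cohort = load_cohort(path, md, grid)
        assert len(cohort) == 2
        assert cohort.subjects[0].gose_category == 2  # GOSE 6 -> category 2

    def test_duplicate_id_rejected(self, grid, tmp_path):
        path, md = self._write_manifest(tmp_path, grid, [self._row("s1"), self._row("s1")])
        with pytest.raises(DuplicateSubjectError):
            load_cohort(path, md, grid)

    def test_severity_gcs_contradiction_rejected(self, grid, tmp_path):
        path, md = self._write_manifest(
            tmp_path, grid, [self._row("s1", severity="moderate", gcs=6)]
        )
        with pytest.raises(SeverityGCSError):
            load_cohort(path, md, grid)

    def test_missing_gose_retained(self, grid, tmp_path):
        path, md = self._write_manifest(tmp_path, grid, [self._row("s1", gose=None)])
        cohort = load_cohort(path, md, grid)
        assert cohort.subjects[0].gose is None

    def test_save_then_load_round_trip(self, grid, tiny_cohort, tmp_path):
        manifest = save_cohort(tiny_cohort, tmp_path / "out")
        back = load_cohort(manifest, tmp_path / "out" / "masks", grid)
        assert len(back) == len(tiny_cohort)
        for a, b in zip(tiny_cohort.subjects, back.subjects):
            assert np.array_equal(a.masks[TOTAL].data, b.masks[TOTAL].data)
            assert a.gose == b.gose


class TestRegionPresence:
    def test_single_lesion_single_region(self, grid, atlas):
        vox = tuple(np.argwhere(atlas.region_mask("temporal_L"))[0])
        cohort = Cohort(grid, [make_subject(grid, "a", [vox])])
        tab = tabulate_region_presence(cohort, atlas).set_index("region")
        assert tab.loc["temporal", "n_all"] == 1
        assert tab.drop("temporal").n_all.sum() == 0

    def test_bilateral_lesion_counts_subject_once(self, grid, atlas):
        left = tuple(np.argwhere(atlas.region_mask("frontal_L"))[0])
        right = tuple(np.argwhere(atlas.region_mask("frontal_R"))[0])
        cohort = Cohort(grid, [make_subject(grid, "a", [left, right])])
        tab = tabulate_region_presence(cohort, atlas).set_index("region")
        assert tab.loc["frontal", "n_all"] == 1

    def test_stratified_by_severity(self, grid, atlas, tiny_cohort):
        tab = tabulate_region_presence(tiny_cohort, atlas)
        assert (tab.n_all == tab.n_severe + tab.n_moderate).all()

    def test_grid_mismatch_rejected(self, atlas):
        other = VoxelGrid.default((16, 16, 16), 3.0)
        cohort = Cohort(other, [])
        with pytest.raises(GridMismatchError):
            tabulate_region_presence(cohort, atlas)
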