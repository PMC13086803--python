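from itertools import permutations

import numpy as np
import pytest

from lesionmap import (
    Cohort,
    FrequencyMap,
    TOTAL,
    VLSMParams,
    inclusion_mask,
    pooled_t,
    run_vlsm,
)
from lesionmap.vlsm import _critical_value, _t_matrix, permutation_threshold

from conftest import make_subject


class TestPooledT:
    def test_equal_means_give_zero(self):
        t, df = pooled_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert df == 4

    def test_known_value(self):
        # classical pooled-variance t for {1,2,3} vs {4,5,6}
        t, df = pooled_t([1, 2, 3], [4, 5, 6])
        assert round(t, 3) == -3.674
        assert df == 4

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=5), rng.normal(1, 1, size=7)
        t1, _ = pooled_t(a, b)
        t2, _ = pooled_t(b, a)
        assert np.isclose(t1, -t2)

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(0.5, 2, size=9)
        t, df = pooled_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert np.isclose(t, ref.statistic)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pooled_t([2, 2, 2], [2, 2])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            pooled_t([1], [2, 3])

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        L = rng.random((12, 6)) > 0.5
        L[:3, :] = True  # ensure both groups exist
        L[-3:, :] = False
        y = rng.normal(size=12)
        t_vec = _t_matrix(L, y[:, None])[:, 0]
        for v in range(6):
            t_ref, _ = pooled_t(y[L[:, v]], y[~L[:, v]])
            assert np.isclose(t_vec[v], t_ref)


class TestInclusionMask:
    @pytest.mark.parametrize("count,included", [(2, False), (3, True), (4, True)])
    def test_min_overlap_boundary(self, grid, count, included):
        counts = np.zeros(grid.shape, int)
        counts[5, 5, 5] = count
        fmap = FrequencyMap(grid, counts, 10, "t", TOTAL)
        mask = inclusion_mask(fmap, VLSMParams(min_overlap=3))
        assert bool(mask[5, 5, 5]) is included

    def test_upper_bound_needs_nonlesioned(self, grid):
        counts = np.zeros(grid.shape, int)
        counts[5, 5, 5] = 9  # only 1 subject non-lesioned, min_per_group=2
        fmap = FrequencyMap(grid, counts, 10, "t", TOTAL)
        assert not inclusion_mask(fmap, VLSMParams())[5, 5, 5]

    def test_permissive_params_test_every_lesioned_voxel(self, grid):
        counts = np.zeros(grid.shape, int)
        counts[1, 1, 1] = 1
        counts[2, 2, 2] = 9
        fmap = FrequencyMap(grid, counts, 10, "t", TOTAL)
        mask = inclusion_mask(fmap, VLSMParams(min_overlap=1, min_per_group=0))
        assert mask[1, 1, 1] and mask[2, 2, 2]
        assert mask.sum() == 2

    def test_raising_min_overlap_shrinks_mask(self, grid):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 8, grid.shape)
        fmap = FrequencyMap(grid, counts, 10, "t", TOTAL)
        prev = inclusion_mask(fmap, VLSMParams(min_overlap=1, min_per_group=0))
        for mo in (2, 3, 5):
            cur = inclusion_mask(fmap, VLSMParams(min_overlap=mo, min_per_group=0))
            assert np.all(prev | ~cur.astype(bool) | cur <= prev | np.ones_like(cur))
            assert np.all(cur <= prev)
            prev = cur


def _six_subject_cohort(grid):
    """Six subjects, two informative voxels."""
    va, vb = (10, 10, 10), (12, 12, 12)
    lesions = [[va], [va], [va, vb], [vb], [vb], []]
    goses = [2, 3, 4, 6, 7, 8]
    subs = []
    for i, (vox, g) in enumerate(zip(lesions, goses)):
        subs.append(make_subject(grid, f"s{i}", vox, gose=g, gcs=6))
    return Cohort(grid, subs), va, vb


class TestPermutationThreshold:
    def test_null_has_n_permutation_entries(self, grid):
        cohort, va, vb = _six_subject_cohort(grid)
        params = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=50, seed=0)
        res = run_vlsm(cohort, params)
        assert len(res.null_max_t) == 50

    def test_alpha_one_makes_every_tested_voxel_significant(self, grid):
        cohort, va, vb = _six_subject_cohort(grid)
        params = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=99,
                            alpha=1.0, seed=0)
        res = run_vlsm(cohort, params)
        assert res.n_tested > 0
        assert np.isclose(res.critical_t, res.null_max_t.min())
        assert res.n_significant == res.n_tested

    def test_monte_carlo_matches_exhaustive_enumeration(self, grid):
        """MC critical |t| and FWE p agree with all 720 outcome orderings."""
        cohort, va, vb = _six_subject_cohort(grid)
        y = np.array([float(s.gose) for s in cohort.subjects])
        L = cohort.lesion_matrix()[:, [np.ravel_multi_index(va, grid.shape),
                                       np.ravel_multi_index(vb, grid.shape)]]
        # exhaustive null of max |t| over the two tested voxels
        exact_max = []
        for perm in permutations(range(6)):
            t = _t_matrix(L, y[list(perm)][:, None])[:, 0]
            exact_max.append(np.nanmax(np.abs(t)))
        exact_max = np.array(exact_max)
        t_obs = _t_matrix(L, y[:, None])[:, 0]
        exact_p = [(1 + (exact_max >= abs(t)).sum()) / (len(exact_max) + 1)
                   for t in t_obs]

        params = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=5000, seed=7)
        null_max, crit = permutation_threshold(L, None, params, outcomes=y)
        # at alpha=0.05 the discrete null puts >5% mass on its own maximum,
        # so both exact and MC thresholds are infinite (nothing significant)
        exact_crit = _critical_value(exact_max, params)
        assert not np.isfinite(exact_crit) and not np.isfinite(crit)
        # at a level the 720-permutation null can resolve, thresholds agree
        loose = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=5000,
                           alpha=0.25, seed=7)
        assert abs(_critical_value(null_max, loose) - _critical_value(exact_max, loose)) <= 0.05
        from lesionmap.vlsm import fwe_p_values

        pm = fwe_p_values(null_max, np.abs(t_obs), params.n_permutations)
        for p_mc, pe in zip(pm, exact_p):
            se = np.sqrt(pe * (1 - pe) / params.n_permutations)
            assert abs(p_mc - pe) <= 3 * se + 1e-9

    def test_seeded_determinism(self, grid):
        cohort, *_ = _six_subject_cohort(grid)
        params = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=200, seed=42)
        r1 = run_vlsm(cohort, params)
        r2 = run_vlsm(cohort, params)
        assert np.array_equal(r1.null_max_t, r2.null_max_t)
        assert np.array_equal(r1.t_map, r2.t_map, equal_nan=True)
        assert np.array_equal(r1.significant_mask, r2.significant_mask)


class TestRunVLSM:
    def test_result_structure(self, grid):
        cohort, va, vb = _six_subject_cohort(grid)
        params = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=100, seed=1)
        res = run_vlsm(cohort, params)
        assert res.n_tested == 2
        assert res.significant_mask[~res.tested_mask].sum() == 0
        p = res.fwe_p_map[res.tested_mask]
        assert np.all((p >= 1 / 101) & (p <= 1.0))
        assert np.all(res.df_map[res.tested_mask] == 4)

    def test_missing_outcome_excluded(self, grid):
        cohort, va, vb = _six_subject_cohort(grid)
        cohort.subjects[0].gose = None
        params = VLSMParams(min_overlap=2, min_per_group=2, n_permutations=50, seed=0)
        res = run_vlsm(cohort, params)
        assert res.n_subjects == 5
        assert res.n_excluded_missing_outcome == 1

    def test_nothing_testable_returns_structured_result(self, grid):
        subs = [make_subject(grid, f"s{i}", [(i, i, i)], gose=4 + i) for i in range(4)]
        res = run_vlsm(Cohort(grid, subs), VLSMParams(min_overlap=3, n_permutations=10))
        assert res.n_tested == 0
        assert res.n_significant == 0
        assert not np.isfinite(res.critical_t)

    def test_degenerate_voxels_flagged_not_tested(self, grid):
        # all lesioned subjects share one outcome value and so do the rest
        subs = [
            make_subject(grid, "a", [(5, 5, 5)], gose=4),
            make_subject(grid, "b", [(5, 5, 5)], gose=4),
            make_subject(grid, "c", [(5, 5, 5)], gose=4),
            make_subject(grid, "d", [], gose=6),
            make_subject(grid, "e", [], gose=6),
        ]
        res = run_vlsm(Cohort(grid, subs), VLSMParams(n_permutations=20, seed=0))
        assert res.n_tested == 0
        assert res.degenerate_mask[5, 5, 5]


class TestFocalEffectPower:
    def test_focal_outcome_effect_is_detected_in_the_focus_region(self, grid, atlas):
        """Positive control: when subjects whose lesions touch a focus
        region have strongly worse outcomes, VLSM localizes at least one
        significant voxel inside that region in most runs.  (Because
        region presence is diffuse on the desk-scale grid, many
        non-lesioned subjects at any given voxel also carry the focal
        effect, so a large shift and n=100 are needed for this power.)"""
        from lesionmap import SyntheticConfig, generate_cohort

        focus = atlas.region_mask("occipital")
        hits = 0
        for s in range(8):
            cfg = SyntheticConfig(n_subjects=100, seed=3000 + s, grid=grid,
                                  atlas=atlas, delta=4.0, focus_region="occipital")
            cohort = generate_cohort(cfg)
            res = run_vlsm(cohort, VLSMParams(n_permutations=500, seed=s))
            hits += bool(np.any(res.significant_mask & focus))
        assert hits >= 6
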