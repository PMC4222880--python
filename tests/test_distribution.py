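"""Centre of gravity, inertia, patches, EOF and pointwise CV."""

import math

import numpy as np
import pytest

from pelagostat.distribution import (
    centre_of_gravity,
    eof,
    identify_patches,
    inertia,
    pointwise_cv,
    year_axis_correlations,
)

from oracles import patch_assignments


class TestGravity:
    def test_midpoint_of_unit_weights(self):
        cg = centre_of_gravity([[0, 0], [2, 0]], [1, 1])
        np.testing.assert_allclose(cg, [1, 0])

    def test_weighted_mean(self):
        cg = centre_of_gravity([[0, 0], [4, 0]], [1, 3])
        np.testing.assert_allclose(cg, [3, 0])

    def test_single_point(self):
        np.testing.assert_allclose(centre_of_gravity([[2.5, -1]], [7]), [2.5, -1])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            centre_of_gravity([[0, 0], [1, 1]], [0, 0])

    def test_two_point_inertia(self):
        g = inertia([[0, 0], [2, 0]], [1, 1])
        assert g.inertia == pytest.approx(1.0)  # (1^2 + 1^2)/2

    def test_point_mass_has_zero_inertia(self):
        g = inertia([[3, 3], [3, 3.0]], [1, 2])
        assert g.inertia == pytest.approx(0.0, abs=1e-12)

    def test_rms_distance_is_sqrt_of_inertia(self, rng):
        # an inertia of 1152 nm^2 corresponds to an RMS distance of ~34 nm
        assert math.sqrt(1152) == pytest.approx(34.0, abs=0.1)
        pts = rng.normal(0, 10, (500, 2))
        w = rng.exponential(1, 500)
        g = inertia(pts, w)
        d2 = ((pts - g.cg) ** 2).sum(axis=1)
        assert g.inertia == pytest.approx(np.average(d2, weights=w))

    def test_axis_variances_sum_to_inertia_and_match_ellipse(self, rng):
        pts = rng.normal(0, 5, (200, 2)) @ np.array([[2, 1], [0, 1.0]])
        w = rng.exponential(1, 200)
        g = inertia(pts, w)
        assert g.axis_variances.sum() == pytest.approx(g.inertia, abs=1e-9)
        assert g.ellipse.semi_major == pytest.approx(math.sqrt(g.axis_variances[0]))
        assert g.ellipse.semi_minor == pytest.approx(math.sqrt(g.axis_variances[1]))

    def test_rotation_invariance(self, rng):
        pts = rng.normal(0, 3, (100, 2))
        w = rng.exponential(1, 100)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        g1 = inertia(pts, w)
        g2 = inertia(pts @ R.T, w)
        assert g2.inertia == pytest.approx(g1.inertia, rel=1e-10)
        np.testing.assert_allclose(g2.cg, R @ g1.cg, atol=1e-10)


class TestPatches:
    def test_single_patch_when_all_points_near_richest(self):
        pts = np.array([[0, 0], [0, 2], [0, 4], [1, 1.0]])
        v = np.array([5.0, 1.0, 1.0, 1.0])
        patches = identify_patches(pts, v, d_along=6, d_across=24)
        assert len(patches) == 1
        assert patches[0].biomass_share == pytest.approx(1.0)

    def test_two_distant_clusters_give_two_equal_patches(self):
        pts = np.array([[0, 0], [0, 1], [100, 0], [100, 1.0]])
        v = np.array([2.0, 2.0, 2.0, 2.0])
        patches = identify_patches(pts, v, d_along=6, d_across=24)
        assert len(patches) == 2
        shares = sorted(p.biomass_share for p in patches)
        assert shares == pytest.approx([0.5, 0.5])

    def test_anisotropy_honoured(self):
        # 10 nm along-transect exceeds the 6-nm threshold -> 2 patches;
        # 10 nm across-transect is inside the 24-nm threshold -> 1 patch
        v = np.array([3.0, 2.0])
        along_pts = np.array([[0, 0], [0, 10.0]])
        across_pts = np.array([[0, 0], [10.0, 0]])
        assert len(identify_patches(along_pts, v, 6, 24)) == 2
        assert len(identify_patches(across_pts, v, 6, 24)) == 1

    def test_partition_and_biomass_accounting(self, rng):
        pts = rng.uniform(0, 60, (40, 2))
        v = rng.exponential(1, 40) * (rng.random(40) > 0.3)
        v[0] = 1.0  # ensure presence
        patches = identify_patches(pts, v, 6, 24)
        all_members = np.concatenate([p.member_indices for p in patches])
        assert len(all_members) == len(set(all_members)) == (v > 0).sum()
        assert sum(p.biomass for p in patches) == pytest.approx(v[v > 0].sum())
        assert sum(p.biomass_share for p in patches) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_recursion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 13)
        pts = rng.uniform(0, 40, (n, 2))
        v = rng.exponential(1, n)
        patches = identify_patches(pts, v, 6, 24)
        oracle = patch_assignments(pts, v, 6, 24)
        ours = np.full(n, -1)
        for k, p in enumerate(patches):
            ours[p.member_indices] = k
        np.testing.assert_array_equal(ours, oracle)

    def test_no_presence_points_rejected(self):
        with pytest.raises(ValueError):
            identify_patches([[0, 0], [1, 1]], [0.0, 0.0], 6, 24)

    def test_small_patches_flagged_not_deleted(self):
        pts = np.array([[0, 0], [100, 0.0]])
        v = np.array([99.0, 1.0])
        patches = identify_patches(pts, v, 6, 24, min_share=0.10)
        assert [p.retained for p in patches] == [True, False]


class TestEof:
    def test_two_identical_years_put_all_variance_on_axis_one(self, rng):
        row = rng.exponential(1, 30)
        res = eof(np.vstack([row, row]), standardization="relative")
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_pct_variance_sums_to_100(self, rng):
        M = rng.exponential(1, (6, 40)) + 0.01
        res = eof(M)
        assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction_from_all_axes(self, rng):
        M = rng.exponential(1, (8, 50)) + 0.01
        res = eof(M, standardization="relative")
        R = M / M.sum(axis=1, keepdims=True)
        err = np.linalg.norm(res.reconstruct() - R) / np.linalg.norm(R)
        assert err < 1e-8

    def test_independent_years_axis_one_near_one_over_nyears(self):
        # 10 x 280 independent rows: leading axis ~ (1+sqrt(10/280))^2/10
        rng = np.random.default_rng(6)
        fracs = [
            eof(rng.normal(10, 1, (10, 280)), standardization="none").pct_variance[0]
            for _ in range(20)
        ]
        assert np.mean(fracs) == pytest.approx(10.0, abs=10.0)

    def test_missing_cells_rejected(self):
        M = np.ones((3, 4))
        M[1, 2] = np.nan
        with pytest.raises(ValueError):
            eof(M)

    def test_year_axis_correlations_bounded(self, rng):
        M = rng.exponential(1, (5, 30)) + 0.01
        res = eof(M)
        corr = year_axis_correlations(res)
        assert np.all(np.abs(corr) <= 1 + 1e-9)


class TestPointwiseCv:
    def test_identical_relative_fields_have_zero_cv(self):
        row = np.array([0.5, 0.3, 0.2])
        cv = pointwise_cv(np.vstack([row, row, row]))
        np.testing.assert_allclose(cv, 0.0, atol=1e-12)

    def test_two_year_formula(self):
        R = np.array([[0.25, 0.75], [0.75, 0.25]])
        cv = pointwise_cv(R)
        # values (0.25, 0.75): mean 0.5, sd sqrt(2)*0.25 -> cv = 0.7071
        np.testing.assert_allclose(cv, math.sqrt(2) / 2, atol=1e-10)

    def test_never_present_location_flagged_nan(self):
        R = np.array([[0.0, 1.0], [0.0, 1.0]])
        cv = pointwise_cv(R)
        assert np.isnan(cv[0]) and cv[1] == 0.0

    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            pointwise_cv(np.array([[0.5, 0.6], [0.5, 0.5]]))

    def test_location_shifts_give_cv_above_one(self):
        # biomass alternating between two sites across 4 years: overdispersed
        R = np.array([[1, 0], [0, 1], [1, 0], [0, 1.0]])
        cv = pointwise_cv(R)
        assert np.all(cv > 1.0)
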