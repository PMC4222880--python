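"""Empirical variography, model fitting, the mean variogram and the
simulation-envelope stability machinery."""

import numpy as np
import pytest

from pelagostat.variogram import (
    EmpiricalVariogram,
    SphericalStructure,
    VariogramModel,
    empirical_variogram,
    fit_variogram_model,
    mean_variogram,
    standardize_by_year,
    variogram_envelope,
)

from oracles import brute_variogram

from pelagostat.variogram import test_annual_stability as check_annual_stability


class TestEmpiricalVariogram:
    def test_two_point_along_pair(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0]])
        e = empirical_variogram(pts, [0.0, 2.0], "along", lag_width=2.0, n_lags=3)
        assert e.gamma[0] == pytest.approx(2.0)  # 0.5 * 2^2
        assert e.n_pairs[0] == 1

    def test_constant_field_has_zero_gamma(self, rng):
        pts = rng.uniform(0, 20, (40, 2))
        e = empirical_variogram(pts, np.full(40, 3.3), "along", angular_tol=90.0)
        assert np.nanmax(e.gamma) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("direction", ["along", "across"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, direction, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 40, (100, 2))
        v = rng.normal(0, 1, 100)
        e = empirical_variogram(pts, v, direction, 2.0, 20, 15.0)
        g_oracle, n_oracle = brute_variogram(pts, v, direction, 2.0, 20, 15.0)
        np.testing.assert_array_equal(e.n_pairs, n_oracle)
        both = np.isfinite(e.gamma)
        np.testing.assert_allclose(e.gamma[both], g_oracle[both], atol=1e-10)

    def test_symmetric_and_shift_invariant(self, rng):
        pts = rng.uniform(0, 30, (60, 2))
        v = rng.normal(0, 1, 60)
        e1 = empirical_variogram(pts, v, "along", angular_tol=90.0)
        e2 = empirical_variogram(pts[::-1], v[::-1], "along", angular_tol=90.0)
        e3 = empirical_variogram(pts, v + 100.0, "along", angular_tol=90.0)
        ok = np.isfinite(e1.gamma)
        np.testing.assert_allclose(e1.gamma[ok], e2.gamma[ok], atol=1e-10)
        np.testing.assert_allclose(e1.gamma[ok], e3.gamma[ok], atol=1e-9)

    def test_empty_lags_flagged_not_error(self):
        pts = np.array([[0.0, 0.0], [0.0, 30.0]])
        e = empirical_variogram(pts, [0.0, 1.0], "along", 2.0, 25)
        assert np.isnan(e.gamma[0])
        assert e.n_pairs[0] == 0


class TestModelFit:
    def test_noise_free_parameters_recovered_to_one_percent(self):
        truth = VariogramModel(0.2, (SphericalStructure(0.8, 10.0, 20.0),))
        lags = (np.arange(25) + 0.5) * 2.0
        emps = {}
        for d in ("along", "across"):
            g = truth.gamma_directional(lags, d)
            emps[d] = EmpiricalVariogram(d, lags, g, np.full(25, 100), lags.copy())
        m = fit_variogram_model(emps["along"], emps["across"], 1)
        assert m.nugget == pytest.approx(0.2, rel=0.01, abs=1e-3)
        s = m.structures[0]
        assert s.sill == pytest.approx(0.8, rel=0.01)
        assert s.range_along == pytest.approx(10.0, rel=0.01)
        assert s.range_across == pytest.approx(20.0, rel=0.01)

    def test_nested_noise_free_fit_recovers_total_sill(self):
        truth = VariogramModel(0.1, (SphericalStructure(0.5, 5.0, 5.0),
                                     SphericalStructure(0.4, 30.0, 30.0)))
        lags = (np.arange(25) + 0.5) * 2.0
        emps = {
            d: EmpiricalVariogram(d, lags, truth.gamma_directional(lags, d),
                                  np.full(25, 100), lags.copy())
            for d in ("along", "across")
        }
        m = fit_variogram_model(emps["along"], emps["across"], 2)
        assert m.total_sill == pytest.approx(1.0, rel=0.02)

    def test_flat_variogram_fits_as_pure_nugget(self):
        lags = (np.arange(10) + 0.5) * 2.0
        flat = EmpiricalVariogram("along", lags, np.full(10, 0.7), np.full(10, 50),
                                  lags.copy())
        flat2 = EmpiricalVariogram("across", lags, np.full(10, 0.7), np.full(10, 50),
                                   lags.copy())
        m = fit_variogram_model(flat, flat2, 1)
        assert m.nugget + sum(s.sill for s in m.structures) == pytest.approx(0.7, abs=0.01)
        # structure either vanishes or degenerates to a flat contribution
        assert m.structures[0].sill < 0.71

    def test_too_few_lags_rejected(self):
        lags = np.array([1.0, 3.0])
        e = EmpiricalVariogram("along", lags, np.array([0.5, 0.6]),
                               np.array([5, 5]), lags.copy())
        with pytest.raises(ValueError):
            fit_variogram_model(e, e, 1)


class TestStandardize:
    def test_mean_zero_variance_one_per_year(self, rng):
        years = np.repeat([2003, 2004, 2005], 50)
        v = rng.normal(5, 3, 150) + np.repeat([0, 10, -4], 50)
        s = standardize_by_year(years, v)
        for y in (2003, 2004, 2005):
            m = years == y
            assert s[m].mean() == pytest.approx(0.0, abs=1e-12)
            assert s[m].var(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        years = np.repeat([1, 2], 40)
        v = rng.normal(0, 2, 80)
        s1 = standardize_by_year(years, v)
        np.testing.assert_allclose(standardize_by_year(years, s1), s1, atol=1e-12)

    def test_zero_variance_year_rejected(self):
        with pytest.raises(ValueError):
            standardize_by_year(np.array([1, 1, 1]), np.array([2.0, 2.0, 2.0]))

    def test_scales_made_comparable_across_years(self, rng):
        # two years with very different scales give comparable sills once
        # standardized (both ~1)
        pts = rng.uniform(0, 40, (120, 2))
        v1 = rng.normal(0, 1, 120)
        v2 = rng.normal(50, 20, 120)
        years = np.repeat([1, 2], 120)
        s = standardize_by_year(years, np.concatenate([v1, v2]))
        g1 = empirical_variogram(pts, s[:120], "along", angular_tol=90.0)
        g2 = empirical_variogram(pts, s[120:], "along", angular_tol=90.0)
        m1 = np.nanmean(g1.gamma[g1.n_pairs > 30])
        m2 = np.nanmean(g2.gamma[g2.n_pairs > 30])
        assert m1 == pytest.approx(1.0, rel=0.25)
        assert m2 == pytest.approx(1.0, rel=0.25)


class TestMeanVariogram:
    def test_identical_years_equal_annual_variogram(self, rng):
        pts = rng.uniform(0, 30, (80, 2))
        v = rng.normal(0, 1, 80)
        mv = mean_variogram([pts, pts, pts], [v, v, v], fit=False)
        annual = empirical_variogram(pts, v, "along")
        ok = np.isfinite(annual.gamma)
        np.testing.assert_allclose(mv.along.gamma[ok], annual.gamma[ok], atol=1e-12)

    def test_pooled_gamma_is_pair_weighted_average(self, rng):
        pts1 = rng.uniform(0, 30, (60, 2))
        pts2 = rng.uniform(0, 30, (90, 2))
        v1 = rng.normal(0, 1, 60)
        v2 = rng.normal(0, 1, 90)
        mv = mean_variogram([pts1, pts2], [v1, v2], fit=False)
        e1 = empirical_variogram(pts1, v1, "along")
        e2 = empirical_variogram(pts2, v2, "along")
        n1, n2 = e1.n_pairs, e2.n_pairs
        with np.errstate(invalid="ignore"):
            expected = (np.nan_to_num(e1.gamma * n1) + np.nan_to_num(e2.gamma * n2)) / (n1 + n2)
        ok = (n1 + n2) > 0
        np.testing.assert_allclose(mv.along.gamma[ok], expected[ok], atol=1e-10)

    def test_no_cross_year_pairs_contribute(self, rng):
        # moving year 2 far away would create cross-year short lags if pairs
        # were pooled across years; the mean variogram must not change
        pts = rng.uniform(0, 30, (50, 2))
        v1 = rng.normal(0, 1, 50)
        v2 = rng.normal(0, 1, 50)
        mv_near = mean_variogram([pts, pts + 0.5], [v1, v2], fit=False)
        mv_far = mean_variogram([pts, pts + 0.5 + np.array([0, 1e6])], [v1, v2], fit=False)
        ok = np.isfinite(mv_near.along.gamma)
        np.testing.assert_allclose(mv_far.along.gamma[ok], mv_near.along.gamma[ok],
                                   atol=1e-10)

    def test_needs_two_years(self, rng):
        pts = rng.uniform(0, 30, (50, 2))
        with pytest.raises(ValueError):
            mean_variogram([pts], [np.zeros(50)])


@pytest.fixture(scope="module")
def setting():
    pts = np.column_stack([np.repeat(np.arange(4) * 12.0, 30),
                           np.tile(np.arange(30.0), 4)])
    model = VariogramModel(0.2, (SphericalStructure(0.8, 10.0, 10.0),))
    return pts, model


class TestEnvelopeAndStability:
    def test_envelope_contains_model_curve_at_interior_lags(self, setting):
        pts, model = setting
        env = variogram_envelope(model, pts, n_sim=500, seed=3, standardize=False)
        for d in ("along", "across"):
            lags = env.lag_centres[d]
            ok = np.isfinite(env.lower[d]) & (lags > 2) & (lags < 25)
            g = model.gamma_directional(lags[ok], d)
            assert np.all(env.lower[d][ok] <= g)
            assert np.all(env.upper[d][ok] >= g)

    def test_degenerate_two_sim_envelope_is_ordered(self, setting):
        pts, model = setting
        env = variogram_envelope(model, pts, n_sim=2, seed=4)
        for d in ("along", "across"):
            ok = np.isfinite(env.lower[d])
            assert np.all(env.lower[d][ok] <= env.upper[d][ok])

    def test_identical_to_model_curve_is_stable(self, setting):
        pts, model = setting
        env = variogram_envelope(model, pts, n_sim=300, seed=5, standardize=False)
        annual = {}
        for d in ("along", "across"):
            lags = env.lag_centres[d]
            g = model.gamma_directional(lags, d)
            annual[d] = EmpiricalVariogram(d, lags, g, np.ones(len(lags), int), lags.copy())
        res = check_annual_stability({2003: annual}, env)[2003]
        assert res.stable

    def test_extreme_variogram_is_unstable(self, setting):
        pts, model = setting
        env = variogram_envelope(model, pts, n_sim=300, seed=5, standardize=False)
        annual = {}
        for d in ("along", "across"):
            lags = env.lag_centres[d]
            g = 10.0 * np.where(np.isfinite(env.upper[d]), env.upper[d], 1.0)
            annual[d] = EmpiricalVariogram(d, lags, g, np.ones(len(lags), int), lags.copy())
        res = check_annual_stability({2003: annual}, env)[2003]
        assert not res.stable
        assert res.frac_outside == pytest.approx(1.0)

    def test_lag_grid_mismatch_rejected(self, setting):
        pts, model = setting
        env = variogram_envelope(model, pts, n_sim=100, seed=6)
        lags = np.arange(1, 11, dtype=float)
        bad = {"along": EmpiricalVariogram("along", lags, np.ones(10),
                                           np.ones(10, int), lags.copy())}
        with pytest.raises(ValueError):
            check_annual_stability({2003: bad}, env)
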