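"""Bayesian inversion: posterior curves, point estimates, HPD regions."""

import numpy as np
import pytest
from scipy.stats import norm

import pubage as pa
from conftest import random_model

BOTH = ["female_model", "male_model"]


@pytest.fixture(params=BOTH)
def model(request):
    return request.getfixturevalue(request.param)


class TestPosteriorCurve:
    def test_density_integrates_to_one(self, model):
        for phase in range(1, 7):
            c = pa.posterior_density(model, phase)
            assert np.trapezoid(c.density, c.grid) == pytest.approx(1.0, abs=1e-6)
            assert np.all(c.density >= 0)

    def test_first_phase_density_decreasing(self, female_model):
        c = pa.posterior_density(female_model, 1)
        assert np.all(np.diff(c.density) < 0)

    def test_last_phase_density_increasing(self, female_model):
        c = pa.posterior_density(female_model, 6)
        assert np.all(np.diff(c.density) > 0)

    def test_matches_independent_quadrature(self, female_model):
        """Oracle: recompute the phase-III posterior directly from Phi
        differences and trapezoidal normalization (any positive scaling of
        the likelihood cancels)."""
        c = pa.posterior_density(female_model, 3, grid_step=0.05)
        t, s = female_model.thresholds, female_model.sigma
        grid = np.arange(17.0, 86.0 + 1e-9, 0.05)
        lik = norm.cdf((t[2] - np.log(grid)) / s) - norm.cdf((t[1] - np.log(grid)) / s)
        for scale in (1.0, 123.4):
            expected = scale * lik / np.trapezoid(scale * lik, grid)
            np.testing.assert_allclose(c.density, expected, rtol=1e-10, atol=1e-12)

    def test_invalid_phase(self, female_model):
        with pytest.raises(pa.DomainError):
            pa.posterior_density(female_model, 0)
        with pytest.raises(pa.DomainError):
            pa.posterior_density(female_model, 7)


class TestPointEstimate:
    def test_interior_modes_match_closed_form(self, model):
        """For interior stages under the uniform prior the mode is
        exp((t_{j-1} + t_j)/2), within one grid step."""
        t = model.thresholds
        for phase in range(2, 6):
            c = pa.posterior_density(model, phase)
            expected = float(np.exp(0.5 * (t[phase - 2] + t[phase - 1])))
            assert pa.point_estimate(c) == pytest.approx(expected, abs=c.grid_step)

    def test_extreme_phases_truncate_at_support(self, model):
        assert pa.point_estimate(pa.posterior_density(model, 1)) == 17.0
        assert pa.point_estimate(pa.posterior_density(model, 6)) == 86.0

    def test_flat_maximum_breaks_ties_low(self):
        c = pa.PosteriorCurve(phase=1, grid=np.linspace(0, 1, 11),
                              density=np.ones(11))
        assert pa.point_estimate(c) == 0.0


class TestHPD:
    def test_nested_and_mass_accurate_reference(self, model):
        for phase in range(1, 7):
            c = pa.posterior_density(model, phase)
            iv50, *_ = pa.hpd_interval(c, 0.5)
            iv95, *_ = pa.hpd_interval(c, 0.95)
            for lo, hi in iv50:
                assert any(L - 1e-9 <= lo and hi <= H + 1e-9 for L, H in iv95)
            cell = c.grid_step * c.density.max()
            for cov, ivs in ((0.5, iv50), (0.95, iv95)):
                mask = np.zeros_like(c.grid, dtype=bool)
                for lo, hi in ivs:
                    mask |= (c.grid >= lo - 1e-12) & (c.grid <= hi + 1e-12)
                assert abs(c.mass(mask) - cov) <= cell + 1e-9

    def test_halving_grid_step_shrinks_mass_error(self, female_model):
        errs = []
        for step in (0.2, 0.1, 0.05):
            c = pa.posterior_density(female_model, 4, grid_step=step)
            ivs, *_ = pa.hpd_interval(c, 0.5)
            mask = np.zeros_like(c.grid, dtype=bool)
            for lo, hi in ivs:
                mask |= (c.grid >= lo - 1e-12) & (c.grid <= hi + 1e-12)
            errs.append(abs(c.mass(mask) - 0.5))
        assert errs[2] <= errs[0] + 1e-12
        assert errs[2] <= 0.05 * c.density.max()

    def test_decreasing_posterior_hpd_is_lower_tail(self, female_model):
        """Phase I: HPD(0.95) = [17, q] with q the 95th posterior percentile."""
        c = pa.posterior_density(female_model, 1)
        ivs, lo_trunc, _ = pa.hpd_interval(c, 0.95)
        assert len(ivs) == 1 and lo_trunc
        lo, hi = ivs[0]
        assert lo == 17.0
        cdf = np.concatenate([[0], np.cumsum(
            0.5 * (c.density[1:] + c.density[:-1]) * np.diff(c.grid))])
        q95 = float(np.interp(0.95, cdf, c.grid))
        assert hi == pytest.approx(q95, abs=2 * c.grid_step)
        assert hi == pytest.approx(36.8, abs=0.5)

    def test_coverage_near_one_fills_support(self, female_model):
        c = pa.posterior_density(female_model, 3)
        ivs, lo_t, hi_t = pa.hpd_interval(c, 0.999999)
        assert lo_t and hi_t
        assert ivs[0][0] == 17.0 and ivs[-1][1] == 86.0

    def test_coverage_domain(self, female_model):
        c = pa.posterior_density(female_model, 2)
        for cov in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(pa.DomainError):
                pa.hpd_interval(c, cov)

    def test_random_models_nestedness(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = random_model(rng)
            phase = int(rng.integers(1, 7))
            c = pa.posterior_density(m, phase, grid_step=0.05)
            iv50, *_ = pa.hpd_interval(c, 0.5)
            iv95, *_ = pa.hpd_interval(c, 0.95)
            for lo, hi in iv50:
                assert any(L - 1e-9 <= lo and hi <= H + 1e-9 for L, H in iv95)


class TestNormedLikelihood:
    def test_max_is_exactly_one(self, model):
        for phase in range(1, 7):
            c = pa.normed_likelihood(model, phase)
            nl = c.normed_likelihood
            assert nl.max() == 1.0
            assert nl[0] <= 1.0 and nl[-1] <= 1.0

    def test_unit_value_at_mode(self, female_model):
        c = pa.normed_likelihood(female_model, 4)
        mode = pa.point_estimate(c)
        assert mode == pytest.approx(44.7, abs=0.1)
        idx = int(np.argmin(np.abs(c.grid - mode)))
        assert c.normed_likelihood[idx] == 1.0


class TestTwoPhaseSymmetry:
    def test_mirror_about_threshold_on_log_scale(self):
        """With one threshold t and support symmetric in log age about t,
        the scaled likelihood curves of the two stages are mirror images:
        lik_2(a) = lik_1(exp(2t - ln a))."""
        t = np.log(40.0)
        m = pa.TransitionModel(thresholds=np.array([t]), sigma=0.3,
                               support=(20.0, 80.0))
        c1 = pa.posterior_density(m, 1, grid_step=0.01)
        c2 = pa.posterior_density(m, 2, grid_step=0.01)
        mirrored = np.exp(2 * t - np.log(c2.grid))
        nl1_at_mirror = np.interp(mirrored, c1.grid, c1.normed_likelihood)
        np.testing.assert_allclose(c2.normed_likelihood, nl1_at_mirror, atol=1e-6)


class TestEstimatorInterface:
    def test_wraps_reference_model(self, female_model):
        est = pa.BayesianAgeEstimator(model=female_model).fit()
        tab = est.summary_table()
        assert list(tab["Phase"]) == [1, 2, 3, 4, 5, 6]
        assert np.all(np.diff(tab["PointEst"]) >= 0)
        preds = est.predict([1, 4, 4, 6])
        np.testing.assert_allclose(preds, [17.0, 44.7, 44.7, 86.0], atol=0.1)

    def test_fits_from_data(self, uniform_female_cohort):
        est = pa.BayesianAgeEstimator(grid_step=0.05).fit(
            uniform_female_cohort["age"].to_numpy()[:800],
            uniform_female_cohort["phase_left"].to_numpy().astype(int)[:800],
        )
        tab = est.summary_table()
        assert tab.shape[0] == 6
        assert np.all(np.diff(tab["PointEst"]) >= 0)

    def test_empty_posterior_error(self):
        m = pa.TransitionModel(thresholds=np.array([0.5, 8.0]), sigma=0.05,
                               support=(17.0, 86.0))
        with pytest.raises(pa.EmptyPosteriorError):
            pa.posterior_density(m, 1)
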