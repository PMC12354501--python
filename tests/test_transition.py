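"""Cumulative-probit transition model: probabilities, fitting, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import pubage as pa
from conftest import random_model


class TestPhaseProbability:
    def test_reference_probabilities_at_age_30(self, female_model):
        """Direct evaluation of the Phi differences at age 30."""
        p = pa.phase_probability(30.0, female_model)
        np.testing.assert_allclose(
            p, [0.121, 0.301, 0.325, 0.193, 0.058, 0.002], atol=5e-4
        )

    def test_cumulative_half_at_threshold_age(self, female_model):
        """At age exp(t_2) the chance of being at or below stage II is exactly 1/2."""
        age = float(np.exp(female_model.thresholds[1]))
        p = pa.phase_probability(age, female_model)
        assert p[:2].sum() == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(0.5, 150.0), st.integers(0, 2**32 - 1))
    def test_probabilities_sum_to_one(self, age, seed):
        model = random_model(np.random.default_rng(seed))
        p = pa.phase_probability(age, model)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(1, 5), st.integers(0, 2**32 - 1))
    def test_exceedance_nondecreasing_in_age(self, j, seed):
        """Pr(stage > j | a) rises monotonically with age (monotone ageing)."""
        model = random_model(np.random.default_rng(seed))
        ages = np.linspace(1.0, 150.0, 400)
        exc = pa.stage_exceedance(ages, model, j)
        assert np.all(np.diff(exc) >= -1e-12)

    def test_nonpositive_age_rejected(self, female_model):
        with pytest.raises(pa.DomainError):
            pa.phase_probability(0.0, female_model)
        with pytest.raises(pa.DomainError):
            pa.phase_probability([-3.0, 20.0], female_model)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(pa.InvalidModelError):
            pa.TransitionModel(thresholds=np.array([3.3, 2.9, 3.6, 4.0, 4.4]), sigma=0.3)
        with pytest.raises(pa.InvalidModelError):
            pa.TransitionModel(thresholds=np.array([2.9, 3.3]), sigma=-0.1)


class TestFit:
    def test_recovers_generating_parameters(self, female_model, fitted_female):
        """n=2000 uniform-age cohort: each threshold within 3 SE of truth,
        sigma within 0.05."""
        m = fitted_female
        assert np.all(
            np.abs(m.thresholds - female_model.thresholds) < 3 * m.standard_errors
        )
        assert abs(m.sigma - female_model.sigma) < 0.05
        assert m.converged

    def test_loglik_no_worse_than_truth(self, female_model, uniform_female_cohort, fitted_female):
        ages = uniform_female_cohort["age"].to_numpy()
        phases = uniform_female_cohort["phase_left"].to_numpy().astype(int)
        p_true = pa.phase_probability(ages, female_model)
        ll_true = np.log(p_true[np.arange(ages.size), phases - 1]).sum()
        assert fitted_female.log_likelihood >= ll_true - 1e-6

    def test_local_optimality(self, uniform_female_cohort, fitted_female):
        """Nearby parameter perturbations never improve the likelihood."""
        ages = uniform_female_cohort["age"].to_numpy()
        phases = uniform_female_cohort["phase_left"].to_numpy().astype(int)
        rng = np.random.default_rng(7)

        def loglik(t, sigma):
            z = (t[None, :] - np.log(ages)[:, None]) / sigma
            cum = np.concatenate(
                [np.zeros((ages.size, 1)), norm.cdf(z), np.ones((ages.size, 1))], axis=1
            )
            p = cum[np.arange(phases.size), phases] - cum[np.arange(phases.size), phases - 1]
            return np.log(np.maximum(p, 1e-300)).sum()

        for _ in range(20):
            dt = rng.normal(scale=0.01, size=fitted_female.thresholds.size)
            ds = rng.normal(scale=0.005)
            t = np.sort(fitted_female.thresholds + dt)
            sigma = max(fitted_female.sigma + ds, 1e-3)
            assert loglik(t, sigma) <= fitted_female.log_likelihood + 1e-6

    def test_single_phase_is_degenerate(self):
        with pytest.raises(pa.DegenerateDataError):
            pa.fit_transition_model([20, 25, 30], [1, 1, 1])

    def test_two_record_threshold_between_ages(self):
        """Phase 1 at 20 and phase 2 at 40 bracket the first transition."""
        m = pa.fit_transition_model([20.0, 40.0], [1, 2])
        assert np.log(20) < m.thresholds[0] < np.log(40)
        # grid-search oracle over (t_1, sigma): nothing beats the fit
        best = -np.inf
        for t1 in np.linspace(np.log(20) + 1e-3, np.log(40) - 1e-3, 60):
            for sigma in np.linspace(0.02, 1.0, 50):
                ll = np.log(norm.cdf((t1 - np.log(20)) / sigma)) + np.log(
                    norm.cdf((np.log(40) - t1) / sigma)
                )
                best = max(best, ll)
        assert m.log_likelihood >= best - 1e-3

    def test_order_invariance_and_duplication(self, uniform_female_cohort):
        ages = uniform_female_cohort["age"].to_numpy()[:400]
        phases = uniform_female_cohort["phase_left"].to_numpy().astype(int)[:400]
        m1 = pa.fit_transition_model(ages, phases)
        perm = np.random.default_rng(3).permutation(ages.size)
        m2 = pa.fit_transition_model(ages[perm], phases[perm])
        np.testing.assert_allclose(m1.thresholds, m2.thresholds, atol=1e-5)
        assert m1.sigma == pytest.approx(m2.sigma, abs=1e-5)

        m3 = pa.fit_transition_model(np.tile(ages, 2), np.tile(phases, 2))
        np.testing.assert_allclose(m1.thresholds, m3.thresholds, atol=1e-4)
        np.testing.assert_allclose(
            m3.standard_errors, m1.standard_errors / np.sqrt(2), rtol=0.05
        )

    def test_estimator_interface(self, uniform_female_cohort):
        """Sklearn-style surface: get_params/set_params/fitted attributes."""
        ta = pa.TransitionAnalysis(random_state=1)
        assert ta.get_params()["random_state"] == 1
        X = uniform_female_cohort["age"].to_numpy()[:500, None]
        y = uniform_female_cohort["phase_left"].to_numpy().astype(int)[:500]
        ta.fit(X, y)
        assert ta.thresholds_.shape == (5,)
        proba = ta.predict_proba([[25.0], [60.0]])
        assert proba.shape == (2, 6)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert set(ta.predict([25.0, 60.0])) <= set(range(1, 7))
        assert ta.score(X, y) == pytest.approx(ta.log_likelihood_ / y.size)


class TestSummary:
    def test_exp_column_is_exp_of_estimate(self, fitted_female):
        tab = pa.age_at_transition_summary(fitted_female)
        body = tab[tab["Parameter"] != "SD"]
        np.testing.assert_allclose(body["expEst"], np.exp(body["Estimate"]))
        assert np.all(np.diff(body["expEst"]) > 0)
        sd = tab[tab["Parameter"] == "SD"].iloc[0]
        assert sd["Estimate"] == pytest.approx(fitted_female.sigma)

    def test_exp_of_zero_is_one(self):
        m = pa.TransitionModel(thresholds=np.array([0.0, 1.0]), sigma=0.5, support=(0.5, 10))
        tab = pa.age_at_transition_summary(m)
        assert tab.loc[0, "expEst"] == pytest.approx(1.0)
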