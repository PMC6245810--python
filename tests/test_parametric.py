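"""Parametric AFT families: special-case identities, ML fitting, delta method."""

import numpy as np
import pytest

from ghostrisk import (
    Cohort,
    CohortScenario,
    FitError,
    fit_parametric,
    generate_cohort,
    logdensity_gengamma,
    nested_loglik_check,
    parametric_risk_curve,
    survival_exponential,
    survival_gengamma,
    survival_weibull,
)


def sim(n, family, params, seed, ltfu=0.0, horizon=1e9):
    return generate_cohort(
        CohortScenario(
            n=n, family=family, family_params=params,
            ltfu_rate=ltfu, admin_horizon=horizon, seed=seed,
        )
    )


class TestSurvivalSpecialCases:
    def test_unit_exponential_at_one(self):
        assert survival_gengamma(1.0, 0.0, 1.0, 1.0) == pytest.approx(np.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (1.3, 0.6), (-0.4, 2.1)])
    def test_kappa_one_reduces_to_weibull(self, t, mu, sigma):
        expected = np.exp(-((t * np.exp(-mu)) ** (1.0 / sigma)))
        assert survival_gengamma(t, mu, sigma, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_kappa_zero_is_lognormal_median(self):
        assert survival_gengamma(1.0, 0.0, 1.0, 0.0) == pytest.approx(0.5, rel=1e-12)

    def test_continuity_in_kappa_at_zero(self):
        s0 = survival_gengamma(1.7, 0.2, 0.9, 0.0)
        for k in (2e-4, -2e-4):
            assert survival_gengamma(1.7, 0.2, 0.9, k) == pytest.approx(s0, abs=2e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            survival_gengamma(-1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            survival_gengamma(1.0, 0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            survival_weibull(0.0, 0.0, 1.0)


class TestNestedIdentities:
    """gengamma(kappa=1) == weibull and weibull(sigma=1) == exponential."""

    @pytest.mark.parametrize("seed", range(5))
    def test_survival_and_density_identities(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, 2)
        sigma = rng.lognormal(0, 0.5)
        t = rng.lognormal(mu, 1.0, 20) + 1e-9
        np.testing.assert_allclose(
            survival_gengamma(t, mu, sigma, 1.0),
            survival_weibull(t, mu, sigma),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            survival_weibull(t, mu, 1.0),
            survival_exponential(t, mu),
            rtol=1e-12,
        )
        z = (np.log(t) - mu) / sigma
        weibull_logpdf = -np.log(sigma * t) + z - np.exp(z)
        np.testing.assert_allclose(
            logdensity_gengamma(t, mu, sigma, 1.0), weibull_logpdf, rtol=1e-12
        )

    def test_loglik_identity_across_families(self):
        """A Weibull fit scored as gengamma(kappa=1) gives the same loglik."""
        cohort = sim(400, "weibull", (1.0, 0.8), seed=2, horizon=6.0)
        from ghostrisk.parametric import _make_nll

        wb = fit_parametric(cohort, "weibull")
        nll_gg = _make_nll("gengamma", cohort)
        nll_wb = _make_nll("weibull", cohort)
        x_wb = np.array([wb.mu, np.log(wb.sigma)])
        x_gg = np.array([wb.mu, np.log(wb.sigma), 1.0])
        assert nll_gg(x_gg) == pytest.approx(nll_wb(x_wb), rel=1e-12)


class TestExponentialClosedForm:
    def test_two_event_hand_example(self):
        """Events at t=2 and t=4: rate 1/3, loglik 2 log(1/3) - 2."""
        fit = fit_parametric(Cohort.from_arrays([2.0, 4.0], [1, 1]), "exponential")
        assert fit.rate == pytest.approx(1 / 3, rel=1e-6)
        assert fit.loglik == pytest.approx(2 * np.log(1 / 3) - 2.0, rel=1e-9)
        assert fit.n_free == 1
        assert fit.sigma == 1.0 and fit.kappa == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_optimizer_matches_events_over_person_time(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        time = rng.exponential(2.0, n) + 1e-3
        event = (rng.random(n) < 0.6).astype(int)
        event[0] = 1
        weight = rng.choice([1.0, 1.5], n)
        cohort = Cohort.from_arrays(time, event, weight)
        fit = fit_parametric(cohort, "exponential")
        closed = cohort.n_events / float(np.dot(cohort.weight, cohort.time))
        assert fit.rate == pytest.approx(closed, rel=1e-6)

    def test_all_censored_rejected(self):
        with pytest.raises(FitError, match="event"):
            fit_parametric(Cohort.from_arrays([1.0, 2.0], [0, 0]), "exponential")

    def test_too_few_events_for_gengamma(self):
        with pytest.raises(FitError):
            fit_parametric(Cohort.from_arrays([1.0, 2.0, 3.0], [1, 1, 0]), "gengamma")


class TestDeltaMethod:
    def test_matches_analytic_exponential(self):
        """SE(F(t)) = t exp(-lambda t) lambda / sqrt(D) for the exponential."""
        cohort = Cohort.from_arrays([2.0, 4.0], [1, 1])
        fit = fit_parametric(cohort, "exponential")
        lam = fit.rate
        curve = parametric_risk_curve(fit, np.array([2.0]))
        analytic_se = 2.0 * np.exp(-2.0 * lam) * lam / np.sqrt(2.0)
        assert curve.risk[0] == pytest.approx(1 - np.exp(-2 * lam), rel=1e-9)
        assert curve.se[0] == pytest.approx(analytic_se, rel=1e-6)

    def test_risk_curve_shape_invariants(self):
        cohort = sim(800, "weibull", (1.2, 0.7), seed=9, horizon=6.0)
        fit = fit_parametric(cohort, "weibull")
        grid = np.linspace(0.05, 8.0, 50)
        curve = parametric_risk_curve(fit, grid)
        assert np.all(np.diff(curve.risk) > 0)
        assert curve.risk[0] < 0.05  # F -> 0 as t -> 0+
        assert np.allclose(curve.cl_upper - curve.cl_lower, 2 * curve.meta["z"] * curve.se)

    def test_nonconverged_fit_refused(self):
        cohort = sim(200, "weibull", (1.2, 0.7), seed=9, horizon=6.0)
        fit = fit_parametric(cohort, "weibull")
        fit.converged = False
        with pytest.raises(FitError, match="non-converged"):
            parametric_risk_curve(fit, np.array([2.0]))
        curve = parametric_risk_curve(fit, np.array([2.0]), force=True)
        assert curve.risk.shape == (1,)


class TestRecoveryAndEfficiency:
    def test_weibull_parameter_recovery(self):
        """Estimates land within 3 reported SEs of the generating values."""
        cohort = sim(2000, "weibull", (1.2, 0.7), seed=17, horizon=5.0)
        assert 0.2 < cohort.event.mean() < 0.9
        fit = fit_parametric(cohort, "weibull")
        se_mu, se_sigma = fit.se()
        assert abs(fit.mu - 1.2) < 3 * se_mu
        assert abs(fit.sigma - 0.7) < 3 * se_sigma

    def test_gengamma_recovers_negative_kappa(self):
        cohort = sim(4000, "gengamma", (1.0, 0.8, -0.6), seed=23, horizon=30.0)
        fit = fit_parametric(cohort, "gengamma")
        assert fit.converged
        se = fit.se()
        assert abs(fit.kappa - (-0.6)) < 4 * se[2]

    def test_se_shrinks_as_inverse_sqrt_n(self):
        """Parametric SE at t=2 scales as 1/sqrt(n) within 10%."""
        ses = []
        for n in (500, 2000, 8000):
            cohort = sim(n, "weibull", (1.2, 0.7), seed=31, horizon=5.0)
            fit = fit_parametric(cohort, "weibull")
            curve = parametric_risk_curve(fit, np.array([2.0]))
            ses.append(curve.se[0])
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.10)
        assert ses[1] / ses[2] == pytest.approx(2.0, rel=0.10)

    def test_weighted_likelihood_acts_as_frequency(self):
        """Doubling all weights doubles loglik and halves the covariance."""
        cohort = sim(300, "weibull", (1.2, 0.7), seed=5, horizon=5.0)
        doubled = cohort.with_weights(cohort.weight * 2.0)
        f1 = fit_parametric(cohort, "weibull")
        f2 = fit_parametric(doubled, "weibull")
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)
        assert f2.mu == pytest.approx(f1.mu, abs=1e-5)
        np.testing.assert_allclose(f2.cov, f1.cov / 2.0, rtol=1e-3)


class TestNestedLogLik:
    def test_ordering_on_simulated_cohort(self):
        cohort = sim(800, "gengamma", (1.0, 0.9, -0.5), seed=3, horizon=20.0)
        nested = nested_loglik_check(cohort)
        assert nested.exponential <= nested.weibull + 1e-4
        assert nested.weibull <= nested.gengamma + 1e-4

    def test_exponential_data_keeps_families_close(self):
        """Under exponential truth the three maximized logliks differ by O_p(1)."""
        cohort = sim(2000, "exponential", (0.5,), seed=13, horizon=8.0)
        nested = nested_loglik_check(cohort)
        assert nested.gengamma - nested.exponential < 6.0

    def test_misspecification_gap_grows_with_n(self):
        """Heavy left-skew (kappa=-0.8) vs exponential: KL gap grows linearly."""
        gaps = []
        for n in (500, 2000, 8000):
            cohort = sim(n, "gengamma", (1.0, 0.8, -0.8), seed=41, horizon=25.0)
            nested = nested_loglik_check(cohort)
            gaps.append(nested.gengamma - nested.exponential)
        assert gaps[0] < gaps[1] < gaps[2]


def test_lifelines_cross_check_weibull():
    """Independent ML implementation agrees on parameters and loglik."""
    lifelines = pytest.importorskip("lifelines")
    cohort = sim(1500, "weibull", (1.0, 0.6), seed=8, horizon=4.0)
    fit = fit_parametric(cohort, "weibull")
    wf = lifelines.WeibullFitter()
    wf.fit(cohort.time, cohort.event)
    # lifelines: S(t) = exp(-(t/lambda_)**rho_)  =>  mu = log lambda_, sigma = 1/rho_
    assert fit.mu == pytest.approx(np.log(wf.lambda_), rel=1e-4)
    assert fit.sigma == pytest.approx(1.0 / wf.rho_, rel=1e-4)
    assert fit.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)
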