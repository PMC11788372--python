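"""Unit and property tests for the joint likelihood building blocks."""

import numpy as np
import pytest

from scipy.stats import norm

from tmbjoint import (
    Cohort,
    ModelParams,
    PriorSpec,
    hazard,
    joint_loglik,
    log_prior,
    response_probability,
    tte_loglik,
)
from tmbjoint.likelihood import cumulative_hazard, response_loglik


@pytest.fixture()
def params():
    return ModelParams(
        alpha_z=(-0.8,), alpha_m=0.4, beta_z=(1.0,), beta_m=-0.4,
        lam=1.0, sigma_b=0.5,
    )


class TestResponseProbability:
    def test_zero_linear_predictor_is_half(self, params):
        assert response_probability([0.0], 0.0, 0.0, params) == pytest.approx(0.5)

    def test_hand_evaluated_inverse_logit(self):
        # alpha_z*z + alpha_m*tmb = -0.8 + 0.4 = -0.4
        p = ModelParams(alpha_z=(-0.8,), alpha_m=0.4, beta_z=(0.0,), beta_m=0.0,
                        lam=1.0, sigma_b=0.5)
        got = response_probability([1.0], 1.0, 0.0, p)
        assert got == pytest.approx(1 / (1 + np.exp(0.4)), abs=1e-12)
        assert got == pytest.approx(0.4013, abs=5e-5)

    def test_random_effect_saturates_probability(self, params):
        assert response_probability([0.3], 1.0, 50.0, params) > 1 - 1e-12
        assert response_probability([0.3], 1.0, -50.0, params) < 1e-12

    def test_monotone_in_tmb_and_bounded(self, params):
        tmb = np.linspace(-5, 5, 41)
        probs = np.array([response_probability([0.2], t, 0.1, params) for t in tmb])
        assert np.all(np.diff(probs) > 0)  # alpha_m > 0
        assert np.all((probs > 0) & (probs < 1))

    def test_dimension_mismatch_raises(self, params):
        with pytest.raises(ValueError, match="dimension"):
            response_probability([1.0, 2.0], 0.0, 0.0, params)


class TestHazard:
    def test_unit_shape_null_predictor_is_constant_one(self):
        p = ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=1.0, sigma_b=0.5)
        for t in (0.1, 1.0, 7.3):
            assert hazard(t, [0.0], 0.0, 0.0, p) == pytest.approx(1.0)

    def test_weibull_baseline_arithmetic(self):
        # h0(t) = lam * t**(lam-1): lam=2, t=2 -> 4
        p = ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=2.0, sigma_b=0.5)
        assert hazard(2.0, [0.0], 0.0, 0.0, p) == pytest.approx(4.0)

    def test_proportional_hazards_scaling(self, params):
        h1 = hazard(1.7, [0.5], 1.0, 0.0, params)
        h2 = hazard(1.7, [0.5], 1.0, np.log(2.0), params)
        assert h2 == pytest.approx(2.0 * h1)

    def test_nonpositive_time_rejected(self, params):
        with pytest.raises(ValueError):
            hazard(0.0, [0.0], 0.0, 0.0, params)

    def test_cumulative_hazard_increasing(self, params):
        ts = np.linspace(0.1, 9, 50)
        H = np.array([cumulative_hazard(t, [0.2], 0.5, 0.1, params) for t in ts])
        assert np.all(np.diff(H) > 0)


class TestTTELoglik:
    def test_censored_closed_form(self):
        p = ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=1.0, sigma_b=0.5)
        assert tte_loglik(3.0, 0, [0.0], 0.0, 0.0, p) == pytest.approx(-3.0)

    def test_event_closed_form(self):
        p = ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=1.0, sigma_b=0.5)
        assert tte_loglik(1.0, 1, [0.0], 0.0, 0.0, p) == pytest.approx(-1.0)

    def test_density_integrates_to_one(self, params):
        # exp(tte_loglik) with delta=1 is the event-time density given b
        ts = np.linspace(1e-6, 80, 400_000)
        dens = np.exp(tte_loglik(ts, 1, np.tile([0.3], (ts.size, 1)), 1.0, 0.2, params))
        assert np.trapezoid(dens, ts) == pytest.approx(1.0, abs=1e-4)

    def test_decreasing_in_time_when_censored(self, params):
        lls = [tte_loglik(t, 0, [0.1], 0.5, 0.0, params) for t in (1.0, 2.0, 5.0)]
        assert lls[0] > lls[1] > lls[2]


class TestJointLoglik:
    def test_brute_force_integration_oracle(self, tiny_cohort, params):
        got = joint_loglik(tiny_cohort, params, quad_order=40)
        b = np.linspace(-8 * params.sigma_b, 8 * params.sigma_b, 20_001)
        expected = 0.0
        for rec in [tiny_cohort[i] for i in range(3)]:
            integrand = (
                np.exp(response_loglik(rec.response, np.tile(rec.z, (b.size, 1)),
                                       rec.tmb_obs, b, params))
                * np.exp(tte_loglik(rec.time, rec.event, np.tile(rec.z, (b.size, 1)),
                                    rec.tmb_obs, b, params))
                * norm.pdf(b, scale=params.sigma_b)
            )
            expected += np.log(np.trapezoid(integrand, b))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_quadrature_self_consistency(self, tiny_cohort, params):
        assert joint_loglik(tiny_cohort, params, quad_order=30) == pytest.approx(
            joint_loglik(tiny_cohort, params, quad_order=60), abs=1e-8
        )

    def test_order_invariance(self, error_free_sim, params):
        cohort = error_free_sim.observed
        perm = np.random.default_rng(5).permutation(len(cohort))
        shuffled = Cohort(cohort.data.iloc[perm])
        assert joint_loglik(cohort, params) == pytest.approx(
            joint_loglik(shuffled, params), rel=1e-12
        )

    def test_degenerate_random_effect_limit(self, tiny_cohort, params):
        small = params.replace(sigma_b=1e-8)
        got = joint_loglik(tiny_cohort, small, quad_order=21)
        expected = 0.0
        for i in range(3):
            rec = tiny_cohort[i]
            expected += response_loglik(rec.response, rec.z, rec.tmb_obs, 0.0, small)
            expected += tte_loglik(rec.time, rec.event, rec.z, rec.tmb_obs, 0.0, small)
        assert got == pytest.approx(expected, abs=1e-5)

    def test_low_quad_order_rejected(self, tiny_cohort, params):
        with pytest.raises(ValueError):
            joint_loglik(tiny_cohort, params, quad_order=3)


class TestLogPrior:
    def test_matches_independent_density_evaluation(self, params):
        from scipy.stats import gamma as gamma_dist

        spec = PriorSpec()
        got = log_prior(params, spec)
        coefs = [-0.8, 0.4, 1.0, -0.4]
        expected = sum(norm.logpdf(c, scale=10.0) for c in coefs)
        expected += gamma_dist.logpdf(params.lam, 0.001, scale=1000.0)
        tau = params.sigma_b**-2
        expected += gamma_dist.logpdf(tau, 0.001, scale=1000.0)
        expected += np.log(2.0) - 3.0 * np.log(params.sigma_b)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_coefficients_at_zero_equal_normal_normalizers(self):
        p = ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=1.0, sigma_b=1.0)
        spec10 = PriorSpec(coef_sd=10.0)
        spec20 = PriorSpec(coef_sd=20.0)
        part10 = log_prior(p, spec10)
        part20 = log_prior(p, spec20)
        # widening the coefficient prior lowers density at 0 by 4*log(2)
        assert part10 - part20 == pytest.approx(4 * np.log(2.0), rel=1e-10)

    def test_invalid_parameters_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=-1.0, sigma_b=0.5)
        with pytest.raises(ValueError):
            ModelParams(alpha_z=(0.0,), alpha_m=0.0, beta_z=(0.0,), beta_m=0.0,
                        lam=1.0, sigma_b=0.0)


def test_params_vector_round_trip(params):
    vec = params.to_vector()
    back = ModelParams.from_vector(vec, params.p)
    assert np.allclose(back.to_vector(), vec)
    assert back.names() == ["alpha_z", "alpha_m", "beta_z", "beta_m", "lam", "sigma_b"]
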