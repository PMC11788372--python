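"""Sampler correctness: determinism, calibration, limits, cross-checks.

The heavyweight check samples the same marginalized posterior with an
independent affine-invariant ensemble sampler (emcee) and compares the
posterior of the TMB effect by a Kolmogorov-Smirnov distance.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import ks_2samp

from tmbjoint import (
    Cohort,
    JointBayesModel,
    MCMCConfig,
    MisclassPriorSpec,
    PriorSpec,
    TMBErrorSpec,
    fit_bayes_mcm,
    fit_bayes_nm,
    generate_cohort,
    get_preset,
)


CFG = MCMCConfig(seed=33, n_iter=3000, n_burn=1500, n_chains=2)


@pytest.fixture(scope="module")
def nm_fit(error_free_sim):
    return fit_bayes_nm(error_free_sim.observed, config=CFG)


class TestDeterminismAndShapes:
    def test_same_seed_identical_draws(self, error_free_sim):
        cfg = MCMCConfig(seed=7, n_iter=400, n_burn=200, n_chains=2)
        a = fit_bayes_nm(error_free_sim.observed, config=cfg)
        b = fit_bayes_nm(error_free_sim.observed, config=cfg)
        for k in a.sample.draws:
            np.testing.assert_array_equal(a.sample.draws[k], b.sample.draws[k])

    def test_draw_shapes_and_export(self, nm_fit):
        assert nm_fit.sample.n_chains == 2
        assert nm_fit.sample.n_keep == 1500
        frame = nm_fit.sample.to_frame()
        assert len(frame) == 3000
        assert "alpha_m" in frame.columns

    def test_results_accessors(self, nm_fit):
        params = nm_fit.params
        assert params.lam > 0 and params.sigma_b > 0
        assert nm_fit.posterior_response_prob.shape == (200,)
        assert nm_fit.variant == "nm"


class TestPosteriorBehavior:
    def test_recovers_generating_parameters(self, error_free_sim, base_params):
        fit = fit_bayes_nm(error_free_sim.observed, config=CFG)
        summ = fit.summary().table
        truth = dict(zip(base_params.names(), base_params.to_vector()))
        truth["lam"], truth["sigma_b"] = 1.0, 0.5
        for name in ("alpha_z", "alpha_m", "beta_z", "beta_m", "lam"):
            z = abs(summ.loc[name, "mean"] - truth[name]) / summ.loc[name, "sd"]
            assert z < 4.0, f"{name} posterior mean {summ.loc[name,'mean']:.3f}"

    def test_posterior_concentration_with_sample_size(self):
        sd = {}
        for n in (100, 400):
            sim = generate_cohort(get_preset("error_free", seed=99, n=n))
            fit = fit_bayes_nm(
                sim.observed, config=MCMCConfig(seed=5, n_iter=2500, n_burn=1200)
            )
            sd[n] = fit.summary()["beta_m"]["sd"]
        # quadrupling n should halve the posterior SD (allow wide slack)
        ratio = sd[400] / sd[100]
        assert 0.5 * 0.7 < ratio < 0.5 * 1.6

    def test_tight_priors_pull_posterior_toward_prior_center(self, error_free_sim):
        wide = fit_bayes_nm(
            error_free_sim.observed,
            config=MCMCConfig(seed=2, n_iter=2000, n_burn=1000),
        )
        tight = fit_bayes_nm(
            error_free_sim.observed,
            prior=PriorSpec(coef_sd=0.01),
            config=MCMCConfig(seed=2, n_iter=2000, n_burn=1000),
        )
        assert abs(tight.posterior_mean["alpha_m"]) < abs(wide.posterior_mean["alpha_m"])
        assert abs(tight.posterior_mean["alpha_m"]) < 0.05

    def test_weak_data_recovers_prior_scale(self):
        # a single patient carries almost no information about alpha_m
        df = pd.DataFrame(
            {"response": [1], "time": [1.0], "event": [1], "tmb_obs": [0.5],
             "z1": [0.5]}
        )
        fit = fit_bayes_nm(
            Cohort(df),
            config=MCMCConfig(seed=8, n_iter=30_000, n_burn=5_000),
        )
        sd = fit.summary()["alpha_m"]["sd"]
        assert sd == pytest.approx(10.0, rel=0.25)


class TestAgainstReferenceSampler:
    def test_matches_emcee_on_marginalized_posterior(self, error_free_sim):
        """KS distance between the engine's beta_m draws and an emcee run
        targeting the same (analytically marginalized) posterior."""
        import emcee

        cohort = Cohort(error_free_sim.observed.data.iloc[:80])
        z, t, d = cohort.z, cohort.time, cohort.event
        r, m = cohort.response, cohort.tmb_obs
        logt = np.log(t)
        xq, wq = np.polynomial.hermite_e.hermegauss(21)
        logw = np.log(wq) - 0.5 * np.log(2 * np.pi)

        def logpost(th):
            az, am, bz, bm, loglam, logsb = th
            lam, sb = np.exp(loglam), np.exp(logsb)
            if not (0.01 < lam < 20 and 0.005 < sb < 20):
                return -np.inf
            b = sb * xq[None, :]
            lp_r = (z @ [az] + am * m)[:, None] + b
            ll_r = r[:, None] * lp_r - np.logaddexp(0.0, lp_r)
            lp_t = (z @ [bz] + bm * m)[:, None] + b
            ll_t = d[:, None] * (loglam + (lam - 1) * logt[:, None] + lp_t) - np.exp(
                np.minimum(lam * logt[:, None] + lp_t, 500)
            )
            ll = logsumexp(ll_r + ll_t + logw[None, :], axis=1).sum()
            pri = -(az**2 + am**2 + bz**2 + bm**2) / 200.0
            pri += 0.001 * loglam - 0.001 * lam
            tau = sb**-2.0
            pri += 0.001 * np.log(tau) - 0.001 * tau
            return ll + pri

        rng = np.random.default_rng(1)
        start = np.array([-0.8, 0.4, 1.0, -0.4, 0.0, np.log(0.5)])
        walkers = start + 0.05 * rng.standard_normal((16, 6))
        sampler = emcee.EnsembleSampler(16, 6, logpost)
        sampler.run_mcmc(walkers, 4000, progress=False)
        ref = sampler.get_chain(discard=1500, thin=4, flat=True)[:, 3]

        fit = fit_bayes_nm(
            cohort, config=MCMCConfig(seed=21, n_iter=14_000, n_burn=4_000, n_chains=2)
        )
        mine = fit.sample.flat("beta_m")
        ks = ks_2samp(mine, ref).statistic
        assert ks < 0.08, f"KS distance {ks:.3f} against reference sampler"


class TestVariantLimits:
    def test_mcm_pinned_priors_match_nm(self, error_free_sim):
        cfg = MCMCConfig(seed=13, n_iter=2500, n_burn=1200, n_chains=1)
        nm = fit_bayes_nm(error_free_sim.observed, config=cfg)
        mcm = fit_bayes_mcm(
            error_free_sim.observed, mis_prior=MisclassPriorSpec.pinned(),
            config=cfg,
        )
        for name in ("alpha_m", "beta_m", "lam"):
            diff = abs(nm.posterior_mean[name] - mcm.posterior_mean[name])
            mc_sd = np.hypot(nm.summary()[name]["sd"], mcm.summary()[name]["sd"])
            assert diff < 0.5 * mc_sd + 0.05

    def test_ecm_pinned_error_variance_returns_observed_tmb(self, normal_error_sim):
        cfg = MCMCConfig(seed=14, n_iter=1500, n_burn=700, n_chains=1)
        fit = JointBayesModel(
            normal_error_sim.observed, tmb_error=TMBErrorSpec.pinned_no_error()
        ).fit(cfg)
        corr = np.corrcoef(fit.posterior_tmb, normal_error_sim.observed.tmb_obs)[0, 1]
        assert corr > 0.999

    def test_pecm_exposes_both_posterior_columns(self, normal_error_sim):
        cfg = MCMCConfig(seed=15, n_iter=800, n_burn=400, n_chains=1)
        fit = JointBayesModel(
            normal_error_sim.observed,
            tmb_error=TMBErrorSpec(),
            response_error=MisclassPriorSpec(),
        ).fit(cfg)
        assert fit.variant == "pecm"
        aug = fit.augmented_cohort()
        for col in ("tmb_posterior", "y_prob_posterior", "response_prob_posterior"):
            assert col in aug.data.columns

    def test_hierarchical_mode_requires_subgroups(self, error_free_sim):
        with pytest.raises(ValueError, match="subgroup"):
            JointBayesModel(
                error_free_sim.observed,
                response_error=MisclassPriorSpec(hierarchical=True),
            )

    def test_hierarchical_subgroup_fit_runs(self):
        sim = generate_cohort(get_preset("misclass_only", seed=31))
        df = sim.observed.data.copy()
        df["subgroup"] = np.where(np.arange(len(df)) % 2 == 0, "a", "b")
        fit = JointBayesModel(
            Cohort(df), response_error=MisclassPriorSpec(hierarchical=True)
        ).fit(MCMCConfig(seed=17, n_iter=800, n_burn=400, n_chains=1))
        names = fit.sample.parameters
        assert "eta_1" in names and "eta_2" in names and "delta_2" in names
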