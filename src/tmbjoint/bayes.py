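"""Bayesian fits of the joint response/survival model and its error-control
variants.

Four variants share one data-augmentation sampler:

* **NM** (naive): no error model; observed response and TMB are taken at
  face value.
* **ECM**: additive TMB measurement error ``TMB* = TMB + e`` with both the
  error density and the true-TMB density modeled as truncated DP Gaussian
  mixtures; the per-patient true TMB is a latent variable.
* **MCM**: response misclassification with sensitivity/specificity
  ``(eta, delta)`` under informative Beta priors; the true response state is
  a latent variable updated from its exact full conditional.
* **PECM**: both channels at once.

The kernel is Metropolis-within-Gibbs: adaptive random-walk blocks for the
regression coefficients and ``log lam``, a conjugate gamma update for the
random-effect precision, vectorized per-patient random-walk updates for the
random effects and latent TMB, exact Bernoulli updates for latent responses,
and conjugate Beta (or logit-normal random-walk, in the hierarchical case)
updates for ``eta``/``delta``.  Proposal scales adapt only during burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort
from .dpmix import DPMixtureSpec, gibbs_sweep, init_state
from .likelihood import ModelParams, PriorSpec, _gamma_logpdf
from .mcmc import (
    AdaptiveScale,
    MCMCConfig,
    PosteriorSample,
    PosteriorSummary,
    diagnostics as _diagnostics,
    summarize,
)
from .misclass import MisclassPriorSpec

__all__ = [
    "TMBErrorSpec",
    "JointBayesModel",
    "BayesResults",
    "fit_bayes_nm",
    "fit_bayes_ecm",
    "fit_bayes_mcm",
    "fit_bayes_pecm",
]


@dataclass
class TMBErrorSpec:
    """DP-mixture hyperparameters for the two deconvolution densities.

    ``error`` governs f_e (base measure centered at 0); ``tmb`` governs
    f_TMB (base center defaults to the sample mean of observed TMB at fit
    time).  ``recenter`` applies the per-sweep mean-zero constraint on f_e,
    absorbing the shift into f_TMB and the latent TMB values.
    """

    error: DPMixtureSpec = field(default_factory=lambda: DPMixtureSpec(m0=0.0))
    tmb: DPMixtureSpec | None = None
    recenter: bool = True

    @classmethod
    def pinned_no_error(cls, variance: float = 1e-6) -> "TMBErrorSpec":
        """Error variance pinned near zero (no-measurement-error limit)."""
        a0 = 1e4
        return cls(error=DPMixtureSpec(m0=0.0, k0=1e4, a0=a0, b0=variance * (a0 - 1)),
                   recenter=False)


class JointBayesModel:
    """Joint Bayesian model of response and survival with optional error control.

    Parameters
    ----------
    cohort : Cohort
        Observed per-patient data.
    tmb_error : TMBErrorSpec or None
        Activate the DP-mixture TMB measurement-error channel (ECM).
    response_error : MisclassPriorSpec or None
        Activate the response-misclassification channel (MCM).
    prior : PriorSpec
        Priors on the core parameters.

    ``fit`` runs the sampler and returns :class:`BayesResults`.
    """

    def __init__(
        self,
        cohort: Cohort,
        tmb_error: TMBErrorSpec | None = None,
        response_error: MisclassPriorSpec | None = None,
        prior: PriorSpec | None = None,
        tmb_column: str = "tmb_obs",
        response_column: str = "response",
    ):
        self.cohort = cohort
        self.tmb_error = tmb_error
        self.response_error = response_error
        self.prior = prior if prior is not None else PriorSpec()
        self.p = cohort.n_covariates

        self._r = cohort.data[response_column].to_numpy(dtype=float)
        self._t = cohort.time
        self._logt = np.log(self._t)
        self._d = cohort.event
        self._z = cohort.z
        self._m_obs = cohort.data[tmb_column].to_numpy(dtype=float)
        if tmb_error is not None and np.ptp(self._m_obs) < 1e-12:
            warnings.warn(
                "all observed TMB values are equal; the error mixture is "
                "degenerate and the deconvolution is not informative",
                stacklevel=2,
            )
        self._groups = cohort.subgroups
        self._n_groups = cohort.n_subgroups
        if response_error is not None and response_error.hierarchical and self._n_groups < 2:
            raise ValueError(
                "hierarchical eta/delta requested but the cohort has no "
                "subgroup labels"
            )

    # ------------------------------------------------------------------
    @property
    def variant(self) -> str:
        if self.tmb_error is not None and self.response_error is not None:
            return "pecm"
        if self.tmb_error is not None:
            return "ecm"
        if self.response_error is not None:
            return "mcm"
        return "nm"

    def fit(self, config: MCMCConfig) -> "BayesResults":
        """Run the sampler (``config.n_chains`` chains) and collect draws."""
        seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = [self._run_chain(config, np.random.default_rng(s)) for s in seqs]
        names = chains[0][0].keys()
        draws = {k: np.stack([c[0][k] for c in chains]) for k in names}
        latents = {
            k: np.mean([c[1][k] for c in chains], axis=0) for k in chains[0][1]
        }
        accept = {
            k: float(np.mean([c[2][k] for c in chains])) for k in chains[0][2]
        }
        sample = PosteriorSample(draws=draws, latent_means=latents,
                                 accept_rates=accept)
        if min(accept.values()) < 0.02:
            warnings.warn(
                f"very low acceptance rate in blocks "
                f"{[k for k, v in accept.items() if v < 0.02]}; "
                "posterior may be poorly explored",
                stacklevel=2,
            )
        return BayesResults(self, sample, config)

    # ------------------------------------------------------------------
    def _run_chain(self, cfg: MCMCConfig, rng: np.random.Generator):
        n, p = len(self.cohort), self.p
        pr = self.prior
        t, logt, d, z = self._t, self._logt, self._d, self._z
        ecm = self.tmb_error is not None
        mcm = self.response_error is not None

        # --- state -----------------------------------------------------
        az = rng.normal(0.0, 0.1, p)
        am = float(rng.normal(0.0, 0.1))
        bz = rng.normal(0.0, 0.1, p)
        bm = float(rng.normal(0.0, 0.1))
        loglam = float(rng.normal(0.0, 0.05))
        tau = 4.0 * float(np.exp(rng.normal(0.0, 0.1)))  # precision of b
        b = np.zeros(n)
        y = self._r.copy()
        tmb = self._m_obs.copy()

        if mcm:
            mp = self.response_error
            hier = mp.hierarchical
            n_g = self._n_groups if hier else 1
            grp = self._groups if hier else np.zeros(n, dtype=int)
            eta_g = np.full(n_g, mp.eta_a / (mp.eta_a + mp.eta_b))
            delta_g = np.full(n_g, mp.delta_a / (mp.delta_a + mp.delta_b))
        if ecm:
            es = self.tmb_error
            spec_e = es.error
            spec_t = es.tmb if es.tmb is not None else DPMixtureSpec(
                m0=float(np.mean(self._m_obs)))
            mix_e = init_state(self._m_obs - tmb, spec_e)
            mix_e.variances[:] = max(spec_e.b0 / max(spec_e.a0 - 1, 0.5), 1e-8)
            mix_e.means[:] = spec_e.m0
            mix_t = init_state(tmb, spec_t)

        scales = {
            "b": AdaptiveScale(0.8, 0.44),
            "alpha": AdaptiveScale(0.3, cfg.adapt_target),
            "beta": AdaptiveScale(0.3, cfg.adapt_target),
            "loglam": AdaptiveScale(0.15, cfg.adapt_target),
            "bscale": AdaptiveScale(0.3, cfg.adapt_target),
        }
        if ecm:
            scales["tmb"] = AdaptiveScale(0.6, 0.44)
        if mcm and self.response_error.hierarchical:
            scales["eta_delta"] = AdaptiveScale(0.3, cfg.adapt_target)

        coef_var = pr.coef_sd**2

        def resp_ll(lp):  # Bernoulli log-lik given linear predictor
            return y * lp - np.logaddexp(0.0, lp)

        # --- storage ---------------------------------------------------
        pnames = ModelParams(
            alpha_z=np.zeros(p), alpha_m=0.0, beta_z=np.zeros(p), beta_m=0.0,
            lam=1.0, sigma_b=1.0,
        ).names()
        store: dict[str, np.ndarray] = {k: np.empty(cfg.n_keep) for k in pnames}
        if mcm:
            for g in range(n_g):
                suf = f"_{g+1}" if n_g > 1 else ""
                store[f"eta{suf}"] = np.empty(cfg.n_keep)
                store[f"delta{suf}"] = np.empty(cfg.n_keep)
        if ecm:
            store["err_mix_mean"] = np.empty(cfg.n_keep)
            store["err_mix_k"] = np.empty(cfg.n_keep)
        lat_sum = {
            "b": np.zeros(n),
            "response_prob": np.zeros(n),
        }
        if ecm:
            lat_sum["tmb_true"] = np.zeros(n)
        if mcm:
            lat_sum["y_true"] = np.zeros(n)

        keep_idx = 0
        for it in range(cfg.n_iter):
            in_burn = it < cfg.n_burn
            if not in_burn:
                for s in scales.values():
                    s.adapting = False

            base_r = z @ az + am * tmb
            base_t = z @ bz + bm * tmb
            lam = float(np.exp(loglam))
            tlam = np.exp(lam * logt)  # t**lam

            # -- ECM: mixtures (alternate sweeps), then latent TMB ------
            if ecm:
                if it % 2 == 0 or it >= cfg.n_iter - 1:
                    e = self._m_obs - tmb
                    gibbs_sweep(e, mix_e, spec_e, rng)
                    gibbs_sweep(tmb, mix_t, spec_t, rng)
                if es.recenter:
                    shift = mix_e.mixture_mean
                    mix_e.shift(-shift)
                    mix_t.shift(shift)
                    tmb = tmb + shift
                    base_r = base_r + am * shift
                    base_t = base_t + bm * shift

                mu_e = mix_e.means[mix_e.labels]
                s2_e = mix_e.variances[mix_e.labels]
                mu_t = mix_t.means[mix_t.labels]
                s2_t = mix_t.variances[mix_t.labels]
                s = scales["tmb"].scale
                prop = tmb + s * rng.standard_normal(n)
                dm = prop - tmb
                lp_r, lp_r2 = base_r + b, base_r + am * dm + b
                lp_t, lp_t2 = base_t + b, base_t + bm * dm + b
                dll = (
                    resp_ll(lp_r2) - resp_ll(lp_r)
                    + d * bm * dm - tlam * (np.exp(lp_t2) - np.exp(lp_t))
                    - (prop - mu_t) ** 2 / (2 * s2_t)
                    + (tmb - mu_t) ** 2 / (2 * s2_t)
                    - (self._m_obs - prop - mu_e) ** 2 / (2 * s2_e)
                    + (self._m_obs - tmb - mu_e) ** 2 / (2 * s2_e)
                )
                acc = np.log(rng.uniform(size=n)) < dll
                tmb = np.where(acc, prop, tmb)
                scales["tmb"].update(float(np.mean(acc)))
                base_r = z @ az + am * tmb
                base_t = z @ bz + bm * tmb

            # -- MCM: latent responses, then eta/delta ------------------
            if mcm:
                p_true = expit(base_r + b)
                e_i, d_i = eta_g[grp], delta_g[grp]
                like1 = np.where(self._r == 1, e_i, 1.0 - e_i)
                like0 = np.where(self._r == 1, 1.0 - d_i, d_i)
                w1 = like1 * p_true
                prob_y1 = w1 / (w1 + like0 * (1.0 - p_true))
                y = (rng.uniform(size=n) < prob_y1).astype(float)

                if not mp.hierarchical:
                    n11 = float(np.sum((y == 1) & (self._r == 1)))
                    n10 = float(np.sum((y == 1) & (self._r == 0)))
                    n00 = float(np.sum((y == 0) & (self._r == 0)))
                    n01 = float(np.sum((y == 0) & (self._r == 1)))
                    for _ in range(100):
                        e_new = rng.beta(mp.eta_a + n11, mp.eta_b + n10)
                        d_new = rng.beta(mp.delta_a + n00, mp.delta_b + n01)
                        if e_new > 1.0 - d_new:
                            eta_g[0], delta_g[0] = e_new, d_new
                            break
                else:
                    s = scales["eta_delta"].scale
                    acc_sum, n_moves = 0.0, 0
                    for g in range(n_g):
                        idx = grp == g
                        for which in ("eta", "delta"):
                            cur = eta_g[g] if which == "eta" else delta_g[g]
                            mu0 = (mp.logit_mean_eta if which == "eta"
                                   else mp.logit_mean_delta)
                            lo = np.log(cur / (1 - cur))
                            lo2 = lo + s * rng.standard_normal()
                            new = float(expit(lo2))
                            pair = (new, delta_g[g]) if which == "eta" else (eta_g[g], new)
                            if pair[0] <= 1.0 - pair[1]:
                                n_moves += 1
                                continue
                            dll = (
                                _misclass_ll(self._r[idx], y[idx], *pair)
                                - _misclass_ll(self._r[idx], y[idx], eta_g[g], delta_g[g])
                                - (lo2 - mu0) ** 2 / (2 * mp.logit_sd**2)
                                + (lo - mu0) ** 2 / (2 * mp.logit_sd**2)
                            )
                            if np.log(rng.uniform()) < dll:
                                if which == "eta":
                                    eta_g[g] = new
                                else:
                                    delta_g[g] = new
                                acc_sum += 1.0
                            n_moves += 1
                    scales["eta_delta"].update(acc_sum / max(n_moves, 1))

            # -- random effects ----------------------------------------
            s = scales["b"].scale
            prop = b + s * rng.standard_normal(n)
            db = prop - b
            lp_r = base_r + b
            exp_t = tlam * np.exp(base_t)
            dll = (
                resp_ll(base_r + prop) - resp_ll(lp_r)
                + d * db - exp_t * (np.exp(prop) - np.exp(b))
                - 0.5 * tau * (prop**2 - b**2)
            )
            acc = np.log(rng.uniform(size=n)) < dll
            b = np.where(acc, prop, b)
            scales["b"].update(float(np.mean(acc)))

            # -- response coefficients ---------------------------------
            s = scales["alpha"].scale
            step = s * rng.standard_normal(p + 1)
            az2, am2 = az + step[:p], am + step[p]
            lp1 = base_r + b
            lp2 = z @ az2 + am2 * tmb + b
            dll = float(
                np.sum(resp_ll(lp2) - resp_ll(lp1))
                - (np.sum(az2**2) + am2**2 - np.sum(az**2) - am**2) / (2 * coef_var)
            )
            accepted = np.log(rng.uniform()) < dll
            if accepted:
                az, am = az2, am2
                base_r = z @ az + am * tmb
            scales["alpha"].update(float(accepted))

            # -- hazard coefficients -----------------------------------
            s = scales["beta"].scale
            step = s * rng.standard_normal(p + 1)
            bz2, bm2 = bz + step[:p], bm + step[p]
            lp1 = base_t + b
            lp2 = z @ bz2 + bm2 * tmb + b
            dll = float(
                np.sum(d * (lp2 - lp1) - tlam * (np.exp(lp2) - np.exp(lp1)))
                - (np.sum(bz2**2) + bm2**2 - np.sum(bz**2) - bm**2) / (2 * coef_var)
            )
            accepted = np.log(rng.uniform()) < dll
            if accepted:
                bz, bm = bz2, bm2
                base_t = z @ bz + bm * tmb
            scales["beta"].update(float(accepted))

            # -- Weibull shape -----------------------------------------
            s = scales["loglam"].scale
            loglam2 = loglam + s * rng.standard_normal()
            lam2 = float(np.exp(loglam2))
            lp_t = base_t + b
            elp = np.exp(lp_t)
            dll = float(
                np.sum(
                    d * ((loglam2 - loglam) + (lam2 - lam) * logt)
                    - (np.exp(lam2 * logt) - tlam) * elp
                )
                + _gamma_logpdf(lam2, pr.gamma_shape, pr.gamma_rate)
                - _gamma_logpdf(lam, pr.gamma_shape, pr.gamma_rate)
                + (loglam2 - loglam)  # Jacobian of sampling on the log scale
            )
            accepted = np.log(rng.uniform()) < dll
            if accepted:
                loglam, lam = loglam2, lam2
                tlam = np.exp(lam * logt)
            scales["loglam"].update(float(accepted))

            # -- random-effect precision (conjugate) --------------------
            tau = float(
                rng.gamma(pr.gamma_shape + n / 2.0, 1.0 / (pr.gamma_rate + 0.5 * np.sum(b**2)))
            )

            # -- joint (b, tau) scale move ------------------------------
            # rescales all random effects and their SD together, which
            # decouples the otherwise slow-mixing sigma_b direction
            s = scales["bscale"].scale
            eps = s * rng.standard_normal()
            cscale = float(np.exp(eps))
            b2 = cscale * b
            tau2 = tau / cscale**2
            lp_r1, lp_r2 = base_r + b, base_r + b2
            lp_t1, lp_t2 = base_t + b, base_t + b2
            dll = float(
                np.sum(resp_ll(lp_r2) - resp_ll(lp_r1))
                + np.sum(d * (b2 - b) - tlam * (np.exp(lp_t2) - np.exp(lp_t1)))
                + (pr.gamma_shape - 1.0) * np.log(tau2 / tau)
                - pr.gamma_rate * (tau2 - tau)
                - 2.0 * eps  # c**-2 volume factor of the (b, tau) map
            )
            accepted = np.log(rng.uniform()) < dll
            if accepted:
                b, tau = b2, tau2
            scales["bscale"].update(float(accepted))

            # -- store --------------------------------------------------
            if not in_burn and (it - cfg.n_burn) % cfg.thin == 0 and keep_idx < cfg.n_keep:
                vals = np.concatenate(
                    [az, [am], bz, [bm], [lam], [tau**-0.5]]
                )
                for k, v in zip(pnames, vals):
                    store[k][keep_idx] = v
                if mcm:
                    for g in range(n_g):
                        suf = f"_{g+1}" if n_g > 1 else ""
                        store[f"eta{suf}"][keep_idx] = eta_g[g]
                        store[f"delta{suf}"][keep_idx] = delta_g[g]
                if ecm:
                    store["err_mix_mean"][keep_idx] = mix_e.mixture_mean
                    store["err_mix_k"][keep_idx] = mix_e.k_occupied
                lat_sum["b"] += b
                lat_sum["response_prob"] += expit(base_r + b)
                if ecm:
                    lat_sum["tmb_true"] += tmb
                if mcm:
                    lat_sum["y_true"] += y
                keep_idx += 1

        lat = {k: v / max(keep_idx, 1) for k, v in lat_sum.items()}
        acc = {k: v.acceptance_rate for k, v in scales.items()}
        return store, lat, acc


def _misclass_ll(r, y, eta, delta):
    p1 = np.where(y == 1, eta, 1.0 - delta)
    like = np.where(r == 1, p1, 1.0 - p1)
    return float(np.sum(np.log(np.maximum(like, 1e-300))))


class BayesResults:
    """Posterior sample with statsmodels-style accessors.

    ``summary()`` returns the per-parameter posterior mean (the point
    estimator), posterior SD, 95% equal-tailed credible interval, ESS and
    R-hat.  Latent posterior means (``posterior_tmb``,
    ``posterior_response_prob``, ``posterior_y_prob``) support downstream
    threshold localization and ROC analyses.
    """

    def __init__(self, model: JointBayesModel, sample: PosteriorSample,
                 config: MCMCConfig):
        self.model = model
        self.sample = sample
        self.config = config
        self._summary: PosteriorSummary | None = None

    @property
    def variant(self) -> str:
        return self.model.variant

    def summary(self) -> PosteriorSummary:
        if self._summary is None:
            self._summary = summarize(self.sample)
        return self._summary

    @property
    def posterior_mean(self) -> pd.Series:
        return self.summary().mean

    @property
    def posterior_sd(self) -> pd.Series:
        return self.summary().sd

    @property
    def params(self) -> ModelParams:
        """ModelParams assembled from the posterior means."""
        m = self.posterior_mean
        p = self.model.p
        if p == 1:
            az, bz = [m["alpha_z"]], [m["beta_z"]]
        else:
            az = [m[f"alpha_z{i+1}"] for i in range(p)]
            bz = [m[f"beta_z{i+1}"] for i in range(p)]
        return ModelParams(
            alpha_z=np.array(az), alpha_m=float(m["alpha_m"]),
            beta_z=np.array(bz), beta_m=float(m["beta_m"]),
            lam=float(m["lam"]), sigma_b=float(m["sigma_b"]),
        )

    @property
    def posterior_tmb(self) -> np.ndarray:
        """Per-patient posterior mean of the latent true TMB."""
        if "tmb_true" in self.sample.latent_means:
            return self.sample.latent_means["tmb_true"]
        return self.model._m_obs.copy()

    @property
    def posterior_y_prob(self) -> np.ndarray:
        """Per-patient posterior P(true response = 1)."""
        if "y_true" in self.sample.latent_means:
            return self.sample.latent_means["y_true"]
        return self.model._r.copy()

    @property
    def posterior_response_prob(self) -> np.ndarray:
        """Posterior mean of the model response probability expit(lp)."""
        return self.sample.latent_means["response_prob"]

    def diagnostics(self, warn: bool = True) -> pd.DataFrame:
        return _diagnostics(self.sample, warn=warn)

    def augmented_cohort(self) -> Cohort:
        """Cohort with posterior TMB / response columns appended."""
        cols = {"response_prob_posterior": self.posterior_response_prob}
        if "tmb_true" in self.sample.latent_means:
            cols["tmb_posterior"] = self.posterior_tmb
        if "y_true" in self.sample.latent_means:
            cols["y_prob_posterior"] = self.posterior_y_prob
        return self.model.cohort.with_columns(**cols)

    def __repr__(self) -> str:
        return (
            f"<BayesResults variant={self.variant} chains={self.sample.n_chains} "
            f"draws={self.sample.n_keep}>"
        )


# -- spec-level convenience constructors ---------------------------------

def fit_bayes_nm(cohort: Cohort, prior: PriorSpec | None = None,
                 config: MCMCConfig | None = None, **kw) -> BayesResults:
    """Naive joint Bayesian fit (no error model)."""
    return JointBayesModel(cohort, prior=prior, **kw).fit(_cfg(config))


def fit_bayes_ecm(cohort: Cohort, mix: TMBErrorSpec | None = None,
                  prior: PriorSpec | None = None,
                  config: MCMCConfig | None = None, **kw) -> BayesResults:
    """TMB measurement-error correction via DP-mixture deconvolution."""
    mix = mix if mix is not None else TMBErrorSpec()
    return JointBayesModel(cohort, tmb_error=mix, prior=prior, **kw).fit(_cfg(config))


def fit_bayes_mcm(cohort: Cohort, mis_prior: MisclassPriorSpec | None = None,
                  prior: PriorSpec | None = None,
                  config: MCMCConfig | None = None, **kw) -> BayesResults:
    """Response-misclassification correction under Beta priors."""
    mis = mis_prior if mis_prior is not None else MisclassPriorSpec()
    return JointBayesModel(cohort, response_error=mis, prior=prior, **kw).fit(_cfg(config))


def fit_bayes_pecm(cohort: Cohort, mix: TMBErrorSpec | None = None,
                   mis_prior: MisclassPriorSpec | None = None,
                   prior: PriorSpec | None = None,
                   config: MCMCConfig | None = None, **kw) -> BayesResults:
    """Pairwise control: TMB error and response misclassification jointly."""
    mix = mix if mix is not None else TMBErrorSpec()
    mis = mis_prior if mis_prior is not None else MisclassPriorSpec()
    return JointBayesModel(
        cohort, tmb_error=mix, response_error=mis, prior=prior, **kw
    ).fit(_cfg(config))


def _cfg(config: MCMCConfig | None) -> MCMCConfig:
    if config is None:
        raise ValueError("an MCMCConfig with an explicit seed is required")
    return config
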