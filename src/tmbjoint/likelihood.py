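"""Joint response/survival model: likelihood, priors, parameter types.

The observed-data model couples a mixed-effects logistic regression for the
binary tumor response with a Weibull-baseline proportional-hazards model for
the time-to-event endpoint through a shared patient-level random effect
``b_i ~ N(0, sigma_b^2)``:

* response:  logit P(Y_i = 1) = alpha_z' Z_i + alpha_m TMB_i + b_i
* hazard:    h_i(t) = lam * t**(lam - 1) * exp(beta_z' Z_i + beta_m TMB_i + b_i)

The baseline hazard is the unit-scale Weibull ``h0(t) = lam t**(lam-1)``
(cumulative baseline ``t**lam``); any scale is absorbed into the covariate
part, which makes ``lam = 1`` the constant-hazard case.  The marginal
likelihood integrates the random effect out by Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln, logsumexp

from .cohort import Cohort

__all__ = [
    "ModelParams",
    "PriorSpec",
    "response_probability",
    "hazard",
    "cumulative_hazard",
    "response_loglik",
    "tte_loglik",
    "joint_loglik",
    "log_prior",
]


@dataclass
class ModelParams:
    """Parameter vector theta of the joint model.

    ``alpha_*`` are the response (logistic) coefficients, ``beta_*`` the
    log-hazard coefficients, ``lam`` the Weibull baseline shape and
    ``sigma_b`` the SD of the shared random effect.
    """

    alpha_z: np.ndarray
    alpha_m: float
    beta_z: np.ndarray
    beta_m: float
    lam: float
    sigma_b: float

    def __post_init__(self) -> None:
        self.alpha_z = np.atleast_1d(np.asarray(self.alpha_z, dtype=float))
        self.beta_z = np.atleast_1d(np.asarray(self.beta_z, dtype=float))
        if self.alpha_z.shape != self.beta_z.shape:
            raise ValueError("alpha_z and beta_z must have the same length")
        if not (self.lam > 0):
            raise ValueError("Weibull shape lam must be positive")
        if not (self.sigma_b > 0):
            raise ValueError("random-effect SD sigma_b must be positive")

    @property
    def p(self) -> int:
        return self.alpha_z.size

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    # Flat-vector view used by optimizers: (alpha_z, alpha_m, beta_z,
    # beta_m, log lam, log sigma_b).
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.alpha_z,
                [self.alpha_m],
                self.beta_z,
                [self.beta_m],
                [np.log(self.lam)],
                [np.log(self.sigma_b)],
            ]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, p: int) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        return cls(
            alpha_z=vec[:p],
            alpha_m=float(vec[p]),
            beta_z=vec[p + 1 : 2 * p + 1],
            beta_m=float(vec[2 * p + 1]),
            lam=float(np.exp(vec[2 * p + 2])),
            sigma_b=float(np.exp(vec[2 * p + 3])),
        )

    def names(self) -> list[str]:
        p = self.p
        az = [f"alpha_z{i+1}" for i in range(p)] if p != 1 else ["alpha_z"]
        bz = [f"beta_z{i+1}" for i in range(p)] if p != 1 else ["beta_z"]
        return az + ["alpha_m"] + bz + ["beta_m", "lam", "sigma_b"]


@dataclass
class PriorSpec:
    """Non-informative priors: N(0, coef_sd^2) on regression coefficients,
    gamma(shape, rate) on the Weibull shape ``lam`` and on the random-effect
    precision ``sigma_b**-2``."""

    coef_sd: float = 10.0
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001

    def __post_init__(self) -> None:
        if min(self.coef_sd, self.gamma_shape, self.gamma_rate) <= 0:
            raise ValueError("prior hyperparameters must be positive")


def _linear_predictor(z, coef_z, tmb, coef_m, b):
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[-1] != np.atleast_1d(coef_z).size:
        raise ValueError(
            f"covariate dimension {z.shape[-1]} does not match coefficient "
            f"length {np.atleast_1d(coef_z).size}"
        )
    return z @ np.atleast_1d(coef_z) + coef_m * np.asarray(tmb) + np.asarray(b)


def response_probability(z, tmb, b, params: ModelParams):
    """P(response) = inverse-logit of the response linear predictor."""
    lp = _linear_predictor(z, params.alpha_z, tmb, params.alpha_m, b)
    out = expit(lp)
    return out.item() if out.size == 1 else out


def hazard(t, z, tmb, b, params: ModelParams):
    """Instantaneous hazard h0(t) * exp(linear predictor), h0 = lam t**(lam-1)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    lp = _linear_predictor(z, params.beta_z, tmb, params.beta_m, b)
    out = params.lam * t ** (params.lam - 1.0) * np.exp(lp)
    return out.item() if out.size == 1 else out


def cumulative_hazard(t, z, tmb, b, params: ModelParams):
    """H(t) = t**lam * exp(linear predictor); strictly increasing in t."""
    t = np.asarray(t, dtype=float)
    lp = _linear_predictor(z, params.beta_z, tmb, params.beta_m, b)
    out = t**params.lam * np.exp(lp)
    return out.item() if out.size == 1 else out


def response_loglik(y, z, tmb, b, params: ModelParams):
    """Bernoulli log-likelihood of response states under the logistic model."""
    lp = _linear_predictor(z, params.alpha_z, tmb, params.alpha_m, b)
    y = np.asarray(y, dtype=float)
    out = y * lp - np.logaddexp(0.0, lp)
    return out.item() if out.size == 1 else out


def tte_loglik(t, delta, z, tmb, b, params: ModelParams):
    """Censored Weibull-PH log-likelihood: delta*log h(T) - H(T)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("tte_loglik requires T > 0")
    delta = np.asarray(delta, dtype=float)
    lp = _linear_predictor(z, params.beta_z, tmb, params.beta_m, b)
    log_h = np.log(params.lam) + (params.lam - 1.0) * np.log(t) + lp
    big_h = t**params.lam * np.exp(lp)
    out = delta * log_h - big_h
    return out.item() if out.size == 1 else out


def joint_loglik(
    cohort: Cohort,
    params: ModelParams,
    quad_order: int = 21,
    tmb: np.ndarray | None = None,
    response: np.ndarray | None = None,
) -> float:
    """Marginal joint log-likelihood with the random effect integrated out.

    Sums over patients the log of the Gauss-Hermite approximation to
    ``integral p(R|b) p(T,Delta|b) N(b; 0, sigma_b^2) db``.

    Parameters
    ----------
    quad_order : int
        Number of Gauss-Hermite nodes (>= 5); the approximation converges
        monotonically for these smooth integrands.
    tmb, response : arrays, optional
        Override the TMB / response columns (used to evaluate the likelihood
        at latent true values).
    """
    if quad_order < 5:
        raise ValueError("quad_order must be at least 5")
    if not (params.sigma_b > 0):
        raise ValueError("sigma_b must be positive")
    nodes, weights = np.polynomial.hermite_e.hermegauss(quad_order)
    # Probabilists' Hermite: integral f(b) N(b;0,s^2) db ~= sum w_k/sqrt(2pi) f(s x_k)
    b_nodes = params.sigma_b * nodes
    log_w = np.log(weights) - 0.5 * np.log(2.0 * np.pi)

    y = cohort.response if response is None else np.asarray(response, float)
    m = cohort.tmb_obs if tmb is None else np.asarray(tmb, float)
    z, t, d = cohort.z, cohort.time, cohort.event

    # (n, K) log-integrand, vectorized over quadrature nodes
    bcol = b_nodes[None, :]
    lp_r = z @ params.alpha_z + params.alpha_m * m
    lp_t = z @ params.beta_z + params.beta_m * m
    lr = y[:, None] * (lp_r[:, None] + bcol) - np.logaddexp(0.0, lp_r[:, None] + bcol)
    log_h = (
        np.log(params.lam)
        + (params.lam - 1.0) * np.log(t)[:, None]
        + lp_t[:, None]
        + bcol
    )
    big_h = t[:, None] ** params.lam * np.exp(lp_t[:, None] + bcol)
    lt = d[:, None] * log_h - big_h
    return float(np.sum(logsumexp(lr + lt + log_w[None, :], axis=1)))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def log_prior(params: ModelParams, spec: PriorSpec = PriorSpec()) -> float:
    """Log prior density of theta.

    Normal N(0, coef_sd^2) on each regression coefficient; gamma on ``lam``;
    gamma on the precision ``tau = sigma_b**-2``, expressed as a density in
    ``sigma_b`` with the change-of-variable Jacobian ``|d tau / d sigma_b| =
    2 sigma_b**-3`` included, so this is a proper density over
    (coefficients, lam, sigma_b).
    """
    if params.lam <= 0 or params.sigma_b <= 0:
        return -np.inf
    coefs = np.concatenate(
        [params.alpha_z, [params.alpha_m], params.beta_z, [params.beta_m]]
    )
    lp = float(np.sum(stats.norm.logpdf(coefs, scale=spec.coef_sd)))
    lp += _gamma_logpdf(params.lam, spec.gamma_shape, spec.gamma_rate)
    tau = params.sigma_b**-2.0
    lp += _gamma_logpdf(tau, spec.gamma_shape, spec.gamma_rate)
    lp += np.log(2.0) - 3.0 * np.log(params.sigma_b)  # Jacobian d tau/d sigma_b
    return lp
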