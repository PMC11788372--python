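"""Response-misclassification model: eta/delta parameters and Beta priors.

The observed response R is a noisy version of the true state Y with
sensitivity ``eta = P(R=1 | Y=1)`` and specificity ``delta = P(R=0 | Y=0)``,
so that

    P(R=1) = eta * P(Y=1) + (1 - delta) * (1 - P(Y=1)).

Without constraints (eta, delta) are not practically identifiable from
(R, Z, TMB) alone, so the Bayesian misclassification correction relies on
informative Beta priors.  The default priors encode high confidence in the
response labels: ``eta ~ Beta(9, 1)`` (mean 0.900, 95% equal-tailed interval
[0.664, 0.997]) and ``delta ~ Beta(72.5, 2.5)``.  Note the Beta(72.5, 2.5)
mean is 72.5/75 = 0.9667 — the often-quoted 0.98 is its mode (71.5/73), not
its mean; this module always reports exact Beta moments and quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MisclassParams",
    "MisclassPriorSpec",
    "observed_response_probability",
    "beta_prior_summary",
    "latent_response_probability",
]


@dataclass
class MisclassParams:
    """Point values of the misclassification parameters."""

    eta: float
    delta: float

    def __post_init__(self):
        if not (0 < self.eta < 1 and 0 < self.delta < 1):
            raise ValueError("eta and delta must lie in (0, 1)")
        if self.eta < 1.0 - self.delta:
            raise ValueError(
                "eta < 1 - delta corresponds to a label flip and is rejected "
                "as non-identifiable"
            )


@dataclass
class MisclassPriorSpec:
    """Beta prior constants (eps1..eps4) for eta and delta.

    When ``hierarchical`` is set and the cohort carries subgroup labels,
    subgroup-level eta_g/delta_g are sampled on the logit scale under a
    shared normal hyperprior with the given means and SDs.
    """

    eta_a: float = 9.0
    eta_b: float = 1.0
    delta_a: float = 72.5
    delta_b: float = 2.5
    hierarchical: bool = False
    logit_mean_eta: float | None = None  # default: logit of the Beta prior mean
    logit_mean_delta: float | None = None
    logit_sd: float = 0.5

    def __post_init__(self):
        if min(self.eta_a, self.eta_b, self.delta_a, self.delta_b) <= 0:
            raise ValueError("Beta prior constants must be positive")
        if self.logit_mean_eta is None:
            m = self.eta_a / (self.eta_a + self.eta_b)
            self.logit_mean_eta = float(np.log(m / (1 - m)))
        if self.logit_mean_delta is None:
            m = self.delta_a / (self.delta_a + self.delta_b)
            self.logit_mean_delta = float(np.log(m / (1 - m)))

    @classmethod
    def pinned(cls, strength: float = 1e4) -> "MisclassPriorSpec":
        """Priors concentrated at eta = delta = 1 (no-misclassification limit)."""
        return cls(eta_a=strength, eta_b=1.0, delta_a=strength, delta_b=1.0)


def observed_response_probability(p_true, mis: MisclassParams):
    """Map P(Y=1) to P(R=1): eta*p + (1-delta)*(1-p).

    Affine in ``p_true`` with slope ``eta - (1 - delta) >= 0`` under the
    identifiability constraint, so the image is [1-delta, eta].
    """
    p = np.asarray(p_true, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_true must lie in [0, 1]")
    out = mis.eta * p + (1.0 - mis.delta) * (1.0 - p)
    return out.item() if out.size == 1 else out


def latent_response_probability(r, p_true, eta: float, delta: float):
    """P(Y=1 | R, p_true, eta, delta) by Bayes' rule (the augmentation step)."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p_true, dtype=float)
    like1 = np.where(r == 1, eta, 1.0 - eta)
    like0 = np.where(r == 1, 1.0 - delta, delta)
    num = like1 * p
    out = num / (num + like0 * (1.0 - p))
    return out.item() if out.size == 1 else out


def beta_prior_summary(a: float, b: float) -> tuple[float, tuple[float, float]]:
    """Exact mean and 95% equal-tailed interval of Beta(a, b)."""
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    mean = a / (a + b)
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return float(mean), (float(lo), float(hi))
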