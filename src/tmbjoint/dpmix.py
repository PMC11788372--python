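"""Truncated Dirichlet-process Gaussian mixtures.

Used to model, nonparametrically, both the TMB measurement-error density
``f_e`` and the true-TMB density ``f_TMB``.  The DP prior is convolved with
a normal kernel, so each realized density is a Gaussian mixture whose number
of occupied components is determined by the data.  Implementation is the
standard truncated stick-breaking construction with a normal-inverse-gamma
base measure and fully conjugate Gibbs sweeps:

* component assignments: categorical given weights and component params;
* stick weights: Beta(1 + n_k, M + n_{>k});
* component (mu_k, s2_k): normal-inverse-gamma posterior given members.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

__all__ = ["DPMixtureSpec", "MixtureState", "gmm_density", "gmm_logpdf"]


@dataclass
class DPMixtureSpec:
    """Hyperparameters of one truncated DP mixture.

    ``concentration`` is the DP mass M; ``(m0, k0, a0, b0)`` the
    normal-inverse-gamma base measure (s2 ~ InvGamma(a0, b0),
    mu | s2 ~ N(m0, s2/k0)); ``k_max`` the truncation level.
    """

    concentration: float = 1.0
    m0: float = 0.0
    k0: float = 0.1
    a0: float = 2.0
    b0: float = 1.0
    k_max: int = 20

    def __post_init__(self):
        if min(self.concentration, self.k0, self.a0, self.b0) <= 0:
            raise ValueError("DP hyperparameters must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def replace(self, **kw) -> "DPMixtureSpec":
        return replace(self, **kw)


@dataclass
class MixtureState:
    """Current mixture realization: weights, component params, assignments."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K,)
    variances: np.ndarray  # (K,)
    labels: np.ndarray  # (n,) component index per observation

    @property
    def k_occupied(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def mixture_mean(self) -> float:
        return float(self.weights @ self.means)

    def shift(self, delta: float) -> None:
        """Translate the whole mixture by ``delta`` in place."""
        self.means = self.means + delta


def gmm_logpdf(x, weights, means, variances):
    """Log density of a Gaussian mixture, vectorized over x."""
    x = np.asarray(x, dtype=float)
    lw = np.log(np.maximum(weights, 1e-300))
    comp = (
        lw
        - 0.5 * np.log(2.0 * np.pi * variances)
        - (x[..., None] - means) ** 2 / (2.0 * variances)
    )
    return logsumexp(comp, axis=-1)


def gmm_density(x, mix: MixtureState):
    """Density of the mixture: sum_k pi_k N(x; mu_k, s2_k)."""
    out = np.exp(gmm_logpdf(x, mix.weights, mix.means, mix.variances))
    return float(out) if np.ndim(x) == 0 else out


def init_state(x: np.ndarray, spec: DPMixtureSpec) -> MixtureState:
    """Start from a single occupied component at the data's moments."""
    n = x.size
    k = spec.k_max
    weights = np.full(k, 1.0 / k)
    means = np.full(k, float(np.mean(x)))
    var = float(np.var(x)) if np.var(x) > 1e-12 else 1.0
    variances = np.full(k, var)
    return MixtureState(weights, means, variances, np.zeros(n, dtype=int))


def gibbs_sweep(
    x: np.ndarray, state: MixtureState, spec: DPMixtureSpec, rng: np.random.Generator
) -> MixtureState:
    """One full conjugate Gibbs sweep; updates ``state`` in place."""
    k = spec.k_max
    # 1. assignments: vectorized inverse-CDF categorical draw
    logp = (
        np.log(np.maximum(state.weights, 1e-300))
        - 0.5 * np.log(2.0 * np.pi * state.variances)
        - (x[:, None] - state.means) ** 2 / (2.0 * state.variances)
    )
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(x.size) * cdf[:, -1]
    state.labels = (cdf < u[:, None]).sum(axis=1)

    counts = np.bincount(state.labels, minlength=k).astype(float)
    # 2. stick-breaking weights
    tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    v = rng.beta(1.0 + counts, spec.concentration + tail)
    v = np.clip(v, 1e-12, 1.0 - 1e-12)
    v[-1] = 1.0
    logw = np.log(v) + np.concatenate([[0.0], np.cumsum(np.log1p(-v[:-1]))])
    w = np.exp(logw)
    state.weights = w / w.sum()

    # 3. component parameters from the NIG posterior
    sums = np.bincount(state.labels, weights=x, minlength=k)
    sq = np.bincount(state.labels, weights=x**2, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    ss = sq - counts * xbar**2
    kn = spec.k0 + counts
    mn = (spec.k0 * spec.m0 + sums) / kn
    an = spec.a0 + counts / 2.0
    bn = spec.b0 + 0.5 * ss + 0.5 * spec.k0 * counts * (xbar - spec.m0) ** 2 / kn
    state.variances = bn / rng.gamma(an)
    state.means = rng.normal(mn, np.sqrt(state.variances / kn))
    return state
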