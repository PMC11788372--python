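"""MCMC configuration, sample containers, summaries and diagnostics.

The sampling kernels themselves live with the model classes in
:mod:`tmbjoint.bayes`; this module owns the run configuration, the retained
draw container, posterior summarization (the point estimator is the mean of
the retained draws) and convergence diagnostics (split R-hat and effective
sample size via arviz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MCMCConfig",
    "PosteriorSample",
    "PosteriorSummary",
    "summarize",
    "diagnostics",
    "AdaptiveScale",
]


@dataclass
class MCMCConfig:
    """Sampler settings.

    A seed is always required: there is no silent default, every fit is
    reproducible.  Retained draws per chain: (n_iter - n_burn) / thin.
    """

    seed: int
    n_iter: int = 10_000
    n_burn: int = 5_000
    n_chains: int = 2
    thin: int = 1
    adapt_target: float = 0.3  # acceptance-rate target for scalar/block moves

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("MCMCConfig requires an explicit seed")
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")

    @property
    def n_keep(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    def replace(self, **kw) -> "MCMCConfig":
        return replace(self, **kw)


@dataclass
class PosteriorSample:
    """Retained draws, shape (n_chains, n_keep) per named parameter.

    ``latent_means`` carries per-patient posterior means of augmented
    quantities (random effects, latent true TMB, latent true response,
    response probabilities) accumulated over retained sweeps.
    """

    draws: dict[str, np.ndarray]
    latent_means: dict[str, np.ndarray] = field(default_factory=dict)
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_keep(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Flattened draws, one column per parameter (delimited-text export)."""
        return pd.DataFrame({k: self.flat(k) for k in self.draws})


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, SD, equal-tailed 95% CI, diagnostics."""

    table: pd.DataFrame

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def sd(self) -> pd.Series:
        return self.table["sd"]

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    def __repr__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v: .4f}")


def summarize(sample: PosteriorSample) -> PosteriorSummary:
    """Posterior mean / SD / 95% equal-tailed interval per parameter.

    The point estimate is the plain average of the retained draws; the
    interval is the empirical 2.5/97.5 percentile.  Draw-order invariant.
    """
    if sample.n_chains * sample.n_keep < 2:
        raise ValueError("need at least two retained draws to summarize")
    rows = {}
    diag = diagnostics(sample, warn=False)
    for name in sample.parameters:
        x = sample.flat(name)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "ess": diag.loc[name, "ess"] if name in diag.index else np.nan,
            "rhat": diag.loc[name, "rhat"] if name in diag.index else np.nan,
        }
    return PosteriorSummary(pd.DataFrame(rows).T)


def diagnostics(sample: PosteriorSample, warn: bool = True) -> pd.DataFrame:
    """Split R-hat and bulk ESS per parameter (R-hat needs >= 2 chains).

    Flags parameters with R-hat > 1.05 via a warning when ``warn``.
    """
    import arviz as az

    rows = {}
    single_chain = sample.n_chains < 2
    if single_chain and warn:
        warnings.warn("single chain: R-hat omitted", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, x in sample.draws.items():
            ess = float(az.ess(x))
            rhat = np.nan if single_chain else float(az.rhat(x))
            rows[name] = {"ess": ess, "rhat": rhat}
    out = pd.DataFrame(rows).T
    if warn and not single_chain:
        bad = out.index[out["rhat"] > 1.05].tolist()
        if bad:
            warnings.warn(f"R-hat > 1.05 for {bad}; chains may not have converged",
                          stacklevel=2)
    return out


class AdaptiveScale:
    """Robbins-Monro adaptation of a log proposal scale during burn-in.

    The scale is frozen once ``adapting`` is cleared (end of burn-in), so the
    retained draws come from a fixed kernel.
    """

    def __init__(self, scale: float, target: float, decay: float = 0.6):
        self.log_scale = float(np.log(scale))
        self.target = target
        self.decay = decay
        self._t = 0
        self.adapting = True
        self.n_accepted = 0.0
        self.n_proposed = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accepted: float) -> None:
        """Record one move; ``accepted`` is the (mean) acceptance indicator."""
        self.n_accepted += accepted
        self.n_proposed += 1
        if self.adapting:
            self._t += 1
            step = self._t ** (-self.decay)
            self.log_scale += step * (accepted - self.target)
            self.log_scale = float(np.clip(self.log_scale, -10.0, 5.0))

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)
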