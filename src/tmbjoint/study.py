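"""Simulation-study harness: estimator comparison, threshold efficacy, ROC.

``run_estimator_study`` repeats cohort generation and fitting for a list of
estimators and aggregates, per parameter:

* ``fitted`` — mean of the per-replicate point estimates;
* ``bias`` — fitted minus the generation truth;
* ``se`` — mean over replicates of the per-fit uncertainty (posterior SD
  for Bayesian fits, sandwich SE for the corrected score);
* ``sd`` — empirical SD of the point estimates across replicates.

``run_threshold_study`` compares minimum-p thresholds derived per method
(observed columns for the naive and corrected-score fits, posterior TMB
and/or dichotomized posterior response for the error-corrected fits) and
reports per-method between-group p-values.  ``roc_compare`` scores observed,
posterior and true TMB against true response labels by the rank
(Mann-Whitney) AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bayes import JointBayesModel, TMBErrorSpec
from .misclass import MisclassPriorSpec
from .cohort import Cohort
from .corrected_score import CorrectedScoreModel
from .likelihood import PriorSpec
from .mcmc import MCMCConfig
from .simulate import SimConfig, SimulatedCohort, generate_cohort
from .threshold import compare_groups, scan_thresholds

__all__ = [
    "EstimatorStudyResult",
    "ThresholdStudyResult",
    "ROCResult",
    "run_estimator_study",
    "run_threshold_study",
    "roc_compare",
    "auc_rank",
    "perturb_labels",
]

_BAYES_ESTIMATORS = {"true_data", "naive", "ecm", "mcm", "pecm"}
_ALL_ESTIMATORS = _BAYES_ESTIMATORS | {"csm"}


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class EstimatorStudyResult:
    """Aggregated table plus the raw per-replicate estimates."""

    table: pd.DataFrame
    estimates: dict[str, pd.DataFrame]  # estimator -> (n_reps x params)
    uncertainties: dict[str, pd.DataFrame]
    truth: dict[str, float]
    n_reps: int

    def fitted(self, estimator: str, param: str) -> float:
        sel = self.table
        row = sel[(sel["estimator"] == estimator) & (sel["param"] == param)]
        return float(row["fitted"].iloc[0])


def _fit_one(
    estimator: str,
    sim: SimulatedCohort,
    scenario: SimConfig,
    mcmc: MCMCConfig,
    prior: PriorSpec,
    mis_prior: MisclassPriorSpec,
    mix: TMBErrorSpec,
) -> tuple[pd.Series, pd.Series]:
    """Return (point estimates, per-fit uncertainties) for one replicate."""
    cohort = sim.observed
    if estimator == "csm":
        if scenario.err_law is None or scenario.err_law.name != "normal":
            raise ValueError(
                "the corrected score requires a normal TMB error scenario "
                "with known sigma_e"
            )
        res = CorrectedScoreModel(cohort, scenario.err_law.sd).fit()
        est = res.summary()["estimate"]
        return est, res.se.reindex(est.index)

    if estimator == "true_data":
        df = cohort.data.copy()
        df["tmb_obs"] = sim.truth["tmb_true"].to_numpy()
        df["response"] = sim.truth["y_true"].to_numpy()
        model = JointBayesModel(Cohort(df), prior=prior)
    elif estimator == "naive":
        model = JointBayesModel(cohort, prior=prior)
    elif estimator == "ecm":
        model = JointBayesModel(cohort, tmb_error=mix, prior=prior)
    elif estimator == "mcm":
        model = JointBayesModel(cohort, response_error=mis_prior, prior=prior)
    elif estimator == "pecm":
        model = JointBayesModel(
            cohort, tmb_error=mix, response_error=mis_prior, prior=prior
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    res = model.fit(mcmc)
    core = model_param_names(cohort)
    # mean/SD straight from the draws; the full summary (ESS, R-hat) is not
    # needed for the aggregate table and is costly over hundreds of fits
    point = pd.Series({k: float(np.mean(res.sample.flat(k))) for k in core})
    unc = pd.Series({k: float(np.std(res.sample.flat(k), ddof=1)) for k in core})
    return point, unc


def model_param_names(cohort: Cohort) -> list[str]:
    from .likelihood import ModelParams

    p = cohort.n_covariates
    return ModelParams(
        alpha_z=np.zeros(p), alpha_m=0.0, beta_z=np.zeros(p), beta_m=0.0,
        lam=1.0, sigma_b=1.0,
    ).names()


def run_estimator_study(
    scenario: SimConfig,
    estimators: list[str],
    n_reps: int,
    seed: int,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
    mis_prior: MisclassPriorSpec | None = None,
    mix: TMBErrorSpec | None = None,
) -> EstimatorStudyResult:
    """Replicate generate-and-fit and aggregate bias/SE/SD per estimator.

    Per-replicate seeds come from a spawned seed sequence, so growing
    ``n_reps`` reproduces the earlier replicates exactly.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    unknown = set(estimators) - _ALL_ESTIMATORS
    if unknown:
        raise ValueError(f"unknown estimators {sorted(unknown)}")
    prior = prior if prior is not None else PriorSpec()
    mis_prior = mis_prior if mis_prior is not None else MisclassPriorSpec()
    mix = mix if mix is not None else TMBErrorSpec()
    base_mcmc = mcmc if mcmc is not None else MCMCConfig(seed=0, n_iter=4000, n_burn=2000)

    truth_params = scenario.params
    truth = dict(
        zip(
            truth_params.names(),
            np.concatenate(
                [
                    truth_params.alpha_z,
                    [truth_params.alpha_m],
                    truth_params.beta_z,
                    [truth_params.beta_m, truth_params.lam, truth_params.sigma_b],
                ]
            ),
        )
    )

    rep_seqs = np.random.SeedSequence(seed).spawn(n_reps)
    est_rows: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    unc_rows: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    for rep, seq in enumerate(rep_seqs):
        gen_seq, fit_seq = seq.spawn(2)
        sim = generate_cohort(scenario, rng=np.random.default_rng(gen_seq))
        fit_seqs = fit_seq.spawn(len(estimators))
        for est_name, fseq in zip(estimators, fit_seqs):
            cfg = base_mcmc.replace(seed=_child_seed(fseq))
            point, unc = _fit_one(est_name, sim, scenario, cfg, prior, mis_prior, mix)
            est_rows[est_name].append(point)
            unc_rows[est_name].append(unc)

    estimates = {e: pd.DataFrame(v).reset_index(drop=True) for e, v in est_rows.items()}
    uncertainties = {e: pd.DataFrame(v).reset_index(drop=True) for e, v in unc_rows.items()}

    records = []
    for e in estimators:
        df, dfu = estimates[e], uncertainties[e]
        for param in df.columns:
            if param not in truth:
                continue
            fitted = float(df[param].mean())
            records.append(
                {
                    "estimator": e,
                    "param": param,
                    "fitted": fitted,
                    "bias": fitted - truth[param],
                    "se": float(dfu[param].mean()),
                    "sd": float(df[param].std(ddof=1)),
                    "n_reps": n_reps,
                }
            )
    return EstimatorStudyResult(
        table=pd.DataFrame(records),
        estimates=estimates,
        uncertainties=uncertainties,
        truth=truth,
        n_reps=n_reps,
    )


# ----------------------------------------------------------------------
@dataclass
class ThresholdStudyResult:
    """Per-replicate, per-method thresholds and between-group p-values."""

    table: pd.DataFrame  # rep, method, cutoff, logrank_p, response_p

    def win_fraction(self, method: str, reference: str, metric: str = "response_p") -> float:
        """Fraction of replicates where ``method`` attains p <= reference's."""
        wide = self.table.pivot(index="rep", columns="method", values=metric)
        return float((wide[method] <= wide[reference]).mean())


def _threshold_for_method(method: str, sim: SimulatedCohort, scenario: SimConfig,
                          mcmc: MCMCConfig, min_frac: float,
                          mis_prior: MisclassPriorSpec, mix: TMBErrorSpec):
    cohort = sim.observed
    tmb_col, resp_col, source = None, None, "observed"
    if method in {"nm", "csm"}:
        # neither supplies posterior columns; the scan runs on observed data
        pass
    elif method in {"mcm", "ecm", "pecm"}:
        model = JointBayesModel(
            cohort,
            tmb_error=mix if method in {"ecm", "pecm"} else None,
            response_error=mis_prior if method in {"mcm", "pecm"} else None,
        )
        res = model.fit(mcmc)
        if method in {"ecm", "pecm"}:
            tmb_col, source = res.posterior_tmb, "posterior"
        if method in {"mcm", "pecm"}:
            resp_col = (res.posterior_y_prob > 0.5).astype(int)
    else:
        raise ValueError(f"unknown method {method!r}")
    scan = scan_thresholds(
        cohort, tmb_values=tmb_col, response_values=resp_col,
        min_frac=min_frac, tmb_source=source,
    )
    comp = compare_groups(cohort, scan.cutoff, tmb_values=tmb_col, response_values=resp_col)
    return scan, comp


def run_threshold_study(
    preset: SimConfig,
    methods: list[str],
    n_reps: int,
    seed: int,
    mcmc: MCMCConfig | None = None,
    min_frac: float = 0.10,
    mis_prior: MisclassPriorSpec | None = None,
    mix: TMBErrorSpec | None = None,
) -> ThresholdStudyResult:
    """Compare per-method minimum-p thresholds over seeded replicates."""
    mis_prior = mis_prior if mis_prior is not None else MisclassPriorSpec()
    mix = mix if mix is not None else TMBErrorSpec()
    base_mcmc = mcmc if mcmc is not None else MCMCConfig(seed=0, n_iter=4000, n_burn=2000)
    rows = []
    for rep, seq in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        gen_seq, fit_seq = seq.spawn(2)
        sim = generate_cohort(preset, rng=np.random.default_rng(gen_seq))
        for method, fseq in zip(methods, fit_seq.spawn(len(methods))):
            cfg = base_mcmc.replace(seed=_child_seed(fseq))
            scan, comp = _threshold_for_method(
                method, sim, preset, cfg, min_frac, mis_prior, mix
            )
            rows.append(
                {
                    "rep": rep,
                    "method": method,
                    "cutoff": scan.cutoff,
                    "logrank_p": comp.logrank_p,
                    "response_p": comp.response_p,
                    "combined_p": scan.combined_p,
                }
            )
    return ThresholdStudyResult(table=pd.DataFrame(rows))


# ----------------------------------------------------------------------
@dataclass
class ROCResult:
    """Per-score ROC curves and rank-formula AUCs."""

    auc: dict[str, float]
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula (ties get average ranks)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    n1 = int(np.sum(labels == 1))
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _roc_points(labels: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    lab = np.asarray(labels)[order]
    tp = np.concatenate([[0], np.cumsum(lab == 1)])
    fp = np.concatenate([[0], np.cumsum(lab == 0)])
    return pd.DataFrame({"fpr": fp / max(fp[-1], 1), "tpr": tp / max(tp[-1], 1)})


def roc_compare(truth_labels, tmb_observed, tmb_posterior=None, tmb_true=None) -> ROCResult:
    """AUC of observed / posterior / true TMB against true response labels."""
    cols = {"observed": np.asarray(tmb_observed, float)}
    if tmb_posterior is not None:
        cols["posterior"] = np.asarray(tmb_posterior, float)
    if tmb_true is not None:
        cols["true"] = np.asarray(tmb_true, float)
    labels = np.asarray(truth_labels)
    auc = {k: auc_rank(labels, v) for k, v in cols.items()}
    curves = {k: _roc_points(labels, v) for k, v in cols.items()}
    return ROCResult(auc=auc, curves=curves)


def perturb_labels(
    response: np.ndarray,
    flip_responders: float,
    flip_nonresponders: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Artificially flip a fraction of responder / non-responder labels."""
    r = np.asarray(response).astype(int)
    u = rng.uniform(size=r.shape)
    flipped = np.where(
        r == 1, (u < flip_responders).astype(int) ^ r, (u < flip_nonresponders).astype(int) ^ r
    )
    return flipped
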