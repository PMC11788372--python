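"""Minimum-p localization of the TMB-positive threshold.

Candidate cutoffs are the midpoints between consecutive sorted unique TMB
values whose split keeps at least ``min_frac`` of the cohort on each side.
Each candidate is scored by a two-sample log-rank test on the survival
endpoint, a Fisher exact test on the 2x2 response table, and Fisher's
combination of the two p-values (-2 * sum(log p) ~ chi-square with 4 df
under independence).  The selected threshold minimizes the combined p over
the exhaustive candidate set; ties break toward the smaller cutoff.

Which TMB column (observed, posterior mean, or true) and which response
column (observed, or posterior P(Y=1) dichotomized at 0.5) are scanned is
the caller's choice — error-corrected fits supply their posterior columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import Cohort

__all__ = [
    "ThresholdResult",
    "GroupComparison",
    "scan_thresholds",
    "logrank_test",
    "response_test",
    "km_curve",
    "compare_groups",
]


@dataclass
class ThresholdResult:
    """Selected cutoff plus the full candidate scan."""

    cutoff: float
    scan: pd.DataFrame  # cutoff, n_low, n_high, logrank_p, response_p, combined_p
    tmb_source: str
    groups: np.ndarray  # 1 = TMB-high at the selected cutoff

    @property
    def combined_p(self) -> float:
        row = self.scan.loc[self.scan["cutoff"] == self.cutoff]
        return float(row["combined_p"].iloc[0])

    def to_json_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tmb_source": self.tmb_source,
            "combined_p": self.combined_p,
            "scan": self.scan.to_dict(orient="records"),
        }


@dataclass
class GroupComparison:
    """Between-group efficacy comparison at a fixed cutoff."""

    cutoff: float
    n_low: int
    n_high: int
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    logrank_stat: float
    logrank_p: float
    response_table: np.ndarray  # rows: low/high, cols: non-response/response
    response_p: float

    @property
    def response_rates(self) -> tuple[float, float]:
        tab = self.response_table
        return (
            tab[0, 1] / max(tab[0].sum(), 1),
            tab[1, 1] / max(tab[1].sum(), 1),
        )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and p-value.

    Standard risk-set computation: at each distinct event time the observed
    group-1 event count is compared with its hypergeometric expectation and
    variance given the pooled risk set.  Agrees with
    ``lifelines.statistics.logrank_test`` (see tests).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("logrank_test requires exactly two non-empty groups")
    in1 = groups == labels[1]

    t_sorted = np.sort(times)
    t1_sorted = np.sort(times[in1])
    ut, d_tot = np.unique(times[events == 1], return_counts=True)
    t1_ev = times[(events == 1) & in1]
    d1 = np.zeros(ut.size)
    if t1_ev.size:
        u1, c1 = np.unique(t1_ev, return_counts=True)
        d1[np.searchsorted(ut, u1)] = c1

    n_at = times.size - np.searchsorted(t_sorted, ut, side="left")
    n1_at = t1_sorted.size - np.searchsorted(t1_sorted, ut, side="left")

    frac = n1_at / n_at
    expected = d_tot * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_tot * frac * (1.0 - frac) * (n_at - d_tot) / np.maximum(n_at - 1.0, 1.0)
    var_sum = float(np.sum(var))
    if var_sum <= 0:
        return 0.0, 1.0
    stat = float((np.sum(d1) - np.sum(expected)) ** 2 / var_sum)
    return stat, float(stats.chi2.sf(stat, df=1))


def response_test(table: np.ndarray, method: str = "fisher") -> float:
    """Two-sided association p for a 2x2 response table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("empty group margin in response table")
    if method == "fisher":
        return float(stats.fisher_exact(table)[1])
    if method == "chi2":
        return float(stats.chi2_contingency(table, correction=False)[1])
    raise ValueError("method must be 'fisher' or 'chi2'")


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a (time, survival) table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, float))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def _combined_p(p_logrank: float, p_response: float, mode: str) -> float:
    if mode == "logrank_only":
        return p_logrank
    if mode == "response_only":
        return p_response
    stat = -2.0 * (np.log(max(p_logrank, 1e-300)) + np.log(max(p_response, 1e-300)))
    return float(stats.chi2.sf(stat, df=4))


def scan_thresholds(
    cohort: Cohort,
    tmb_values: np.ndarray | None = None,
    min_frac: float = 0.10,
    response_values: np.ndarray | None = None,
    combine: str = "fisher",
    tmb_source: str = "observed",
) -> ThresholdResult:
    """Exhaustive minimum-p scan over candidate TMB cutoffs.

    Parameters
    ----------
    tmb_values : array, optional
        TMB column to scan (defaults to the observed column).
    min_frac : float in (0, 0.5)
        Minimum fraction of patients that must fall on each side.
    response_values : array, optional
        Binary response column for the 2x2 tests (defaults to observed;
        pass a dichotomized posterior for corrected fits).
    combine : {"fisher", "logrank_only", "response_only"}
    """
    if not (0 < min_frac < 0.5):
        raise ValueError("min_frac must lie in (0, 0.5)")
    tmb = cohort.tmb_obs if tmb_values is None else np.asarray(tmb_values, float)
    resp = cohort.response if response_values is None else np.asarray(response_values)
    times, events = cohort.time, cohort.event
    n = len(cohort)

    uniq = np.unique(tmb)
    if uniq.size < 2:
        raise ValueError("all TMB values are identical; no candidate cutoffs")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_low = np.searchsorted(np.sort(tmb), mids, side="right")
    keep = (n_low >= min_frac * n) & ((n - n_low) >= min_frac * n)
    candidates = mids[keep]
    if candidates.size == 0:
        raise ValueError(
            f"no candidate cutoff keeps at least {min_frac:.0%} of patients "
            "on each side"
        )

    rows = []
    for c in candidates:
        high = tmb > c
        nl, nh = int(n - high.sum()), int(high.sum())
        _, p_lr = logrank_test(times, events, high.astype(int))
        tab = np.array(
            [
                [np.sum((~high) & (resp == 0)), np.sum((~high) & (resp == 1))],
                [np.sum(high & (resp == 0)), np.sum(high & (resp == 1))],
            ]
        )
        p_resp = response_test(tab)
        rows.append(
            {
                "cutoff": float(c),
                "n_low": nl,
                "n_high": nh,
                "logrank_p": p_lr,
                "response_p": p_resp,
                "combined_p": _combined_p(p_lr, p_resp, combine),
            }
        )
    scan = pd.DataFrame(rows)
    best = int(scan["combined_p"].idxmin())  # first minimum -> smaller cutoff
    cutoff = float(scan.loc[best, "cutoff"])
    return ThresholdResult(
        cutoff=cutoff,
        scan=scan,
        tmb_source=tmb_source,
        groups=(tmb > cutoff).astype(int),
    )


def compare_groups(
    cohort: Cohort,
    cutoff: float,
    tmb_values: np.ndarray | None = None,
    response_values: np.ndarray | None = None,
) -> GroupComparison:
    """Split at ``cutoff`` and compare survival (log-rank + KM) and response
    (Fisher exact) between the TMB-low and TMB-high groups."""
    tmb = cohort.tmb_obs if tmb_values is None else np.asarray(tmb_values, float)
    resp = cohort.response if response_values is None else np.asarray(response_values)
    if not (tmb.min() <= cutoff <= tmb.max()):
        raise ValueError("cutoff lies outside the TMB range")
    high = tmb > cutoff
    if high.all() or (~high).all():
        raise ValueError("cutoff does not split the cohort")
    stat, p_lr = logrank_test(cohort.time, cohort.event, high.astype(int))
    tab = np.array(
        [
            [np.sum((~high) & (resp == 0)), np.sum((~high) & (resp == 1))],
            [np.sum(high & (resp == 0)), np.sum(high & (resp == 1))],
        ]
    )
    return GroupComparison(
        cutoff=float(cutoff),
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        km_low=km_curve(cohort.time[~high], cohort.event[~high]),
        km_high=km_curve(cohort.time[high], cohort.event[high]),
        logrank_stat=stat,
        logrank_p=p_lr,
        response_table=tab,
        response_p=response_test(tab),
    )
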