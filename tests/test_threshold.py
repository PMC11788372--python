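"""Threshold localization: log-rank, Fisher tests, KM curves, min-p scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmbjoint import Cohort, compare_groups, km_curve, logrank_test, response_test, scan_thresholds


class TestLogrank:
    def test_exchangeable_groups_give_null_statistic(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        events = np.ones(8)
        groups = np.repeat([0, 1], 4)
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_six_subject_risk_set_table(self):
        # groups: A = {2, 4+, 5}, B = {1, 3, 6+}  ("+" censored)
        times = np.array([2.0, 4.0, 5.0, 1.0, 3.0, 6.0])
        events = np.array([1, 0, 1, 1, 1, 0])
        groups = np.array([0, 0, 0, 1, 1, 1])
        # risk-set walk over event times 1,2,3,5 (group-1 = B):
        #  t=1: n=6, n1=3, d=1 (B) -> E=0.5,   V=0.25
        #  t=2: n=5, n1=2, d=1 (A) -> E=0.4,   V=0.24
        #  t=3: n=4, n1=2, d=1 (B) -> E=0.5,   V=0.25
        #  t=5: n=2, n1=1, d=1 (A) -> E=0.5,   V=0.25
        o_minus_e = (1 + 0 + 1 + 0) - (0.5 + 0.4 + 0.5 + 0.5)
        var = 0.25 + 0.24 + 0.25 + 0.25
        expected = o_minus_e**2 / var
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(expected, abs=1e-10)
        assert 0 < p <= 1

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        times = rng.exponential(1.0, 80)
        times[40:] = rng.exponential(2.0, 40)
        events = rng.uniform(size=80) < 0.8
        groups = np.repeat([0, 1], 40)
        stat, p = logrank_test(times, events.astype(int), groups)
        ref = ll_logrank(times[:40], times[40:], events[:40], events[40:])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestResponseTest:
    def test_balanced_table_gives_p_one(self):
        assert response_test(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_perfect_association_matches_hypergeometric_enumeration(self):
        table = np.array([[10, 0], [0, 10]])
        p = response_test(table)
        # two-sided Fisher p = 2 * P(X = 0) for the central hypergeometric
        expected = 2 * stats.hypergeom.pmf(0, 20, 10, 10)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_label_swap_symmetry(self):
        table = np.array([[12, 3], [6, 9]])
        assert response_test(table) == pytest.approx(response_test(table[::-1]))

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            response_test(np.array([[0, 0], [3, 4]]))


class TestKMCurve:
    def test_all_censored_flat_at_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(curve["survival"].to_numpy() == 1.0)

    def test_product_limit_arithmetic(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        at = curve.set_index("time")["survival"]
        assert at.loc[1.0] == pytest.approx(2 / 3)
        assert at.loc[2.0] == pytest.approx(1 / 3)
        assert at.loc[3.0] == pytest.approx(0.0)

    def test_non_increasing(self):
        rng = np.random.default_rng(3)
        curve = km_curve(rng.exponential(1, 50), rng.uniform(size=50) < 0.7)
        assert np.all(np.diff(curve["survival"]) <= 1e-12)


def _planted_cohort(seed: int, n: int = 500) -> Cohort:
    """Two latent groups split at TMB = 1 with hazard ratio e and odds ratio e."""
    rng = np.random.default_rng(seed)
    tmb = rng.uniform(0, 2, n)
    high = tmb > 1.0
    lp_h = np.where(high, -1.0, 0.0)
    times = rng.exponential(np.exp(-lp_h))
    cens = rng.uniform(0, 10, n)
    t = np.minimum(times, cens)
    d = (times <= cens).astype(int)
    p_resp = 1 / (1 + np.exp(-(np.where(high, 0.5, -0.5))))
    r = (rng.uniform(size=n) < p_resp).astype(int)
    return Cohort(pd.DataFrame({"response": r, "time": t, "event": d, "tmb_obs": tmb}))


class TestScan:
    def test_degenerate_tmb_rejected(self):
        df = pd.DataFrame(
            {"response": [1, 0], "time": [1.0, 2.0], "event": [1, 1],
             "tmb_obs": [2.0, 2.0]}
        )
        with pytest.raises(ValueError, match="identical"):
            scan_thresholds(Cohort(df))

    def test_planted_threshold_recovered(self):
        hits = 0
        for seed in range(50):
            res = scan_thresholds(_planted_cohort(seed))
            hits += 0.8 <= res.cutoff <= 1.2
        assert hits >= 45  # >= 90% of repeats

    def test_scan_invariant_to_patient_order(self):
        cohort = _planted_cohort(7, n=120)
        perm = np.random.default_rng(0).permutation(120)
        shuffled = Cohort(cohort.data.iloc[perm])
        a = scan_thresholds(cohort)
        b = scan_thresholds(shuffled)
        assert a.cutoff == pytest.approx(b.cutoff)
        pd.testing.assert_frame_equal(a.scan, b.scan)

    def test_exhaustive_minimum_and_group_fraction(self):
        cohort = _planted_cohort(3, n=200)
        res = scan_thresholds(cohort, min_frac=0.2)
        assert res.scan["combined_p"].min() == pytest.approx(res.combined_p)
        assert (res.scan[["n_low", "n_high"]] >= 0.2 * 200).all().all()
        assert res.cutoff in res.scan["cutoff"].to_numpy()

    def test_min_frac_validated(self):
        with pytest.raises(ValueError):
            scan_thresholds(_planted_cohort(1), min_frac=0.7)


class TestCompareGroups:
    def test_cutoff_outside_range_rejected(self):
        cohort = _planted_cohort(2, n=100)
        with pytest.raises(ValueError, match="range"):
            compare_groups(cohort, cutoff=-5.0)

    def test_planted_separation_sign(self):
        comp = compare_groups(_planted_cohort(11), cutoff=1.0)
        rate_low, rate_high = comp.response_rates
        assert rate_high > rate_low
        med_low = comp.km_low[comp.km_low["survival"] <= 0.5]["time"].min()
        med_high = comp.km_high[comp.km_high["survival"] <= 0.5]["time"].min()
        assert med_high > med_low

    def test_groups_partition_cohort(self):
        cohort = _planted_cohort(5, n=150)
        comp = compare_groups(cohort, cutoff=1.0)
        assert comp.n_low + comp.n_high == 150
        assert comp.response_table.sum() == 150
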