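"""Cohort statistics against independent oracles (scipy, lifelines, hand
computations and direct enumeration)."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmacotype.cohort_stats import (
    CohortError,
    fisher_exact_two_sided,
    km_curve,
    logrank_test,
    mann_whitney_two_sided,
    pharmacotyping_efficacy,
    prediction_accuracy,
    round_half_up,
    subtype_concordance,
    tumor_control,
)


class TestTumorControl:
    @pytest.mark.parametrize("resp,expected", [
        ("CR", "response"), ("PR", "response"), ("SD", "response"),
        ("PD", "no_response"), ("not_available", "not_available"),
    ])
    def test_mapping(self, resp, expected):
        assert tumor_control(resp) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(CohortError):
            tumor_control("MR")


class TestRounding:
    def test_half_up(self):
        assert round_half_up(63.6363) == 63.6
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(91.15, 1) == 91.2


class TestEfficacy:
    def test_overall_fixture(self, fixture_cohort):
        patients, _ = fixture_cohort
        r = pharmacotyping_efficacy(patients)
        assert (r.percent, r.numerator, r.denominator) == (63.6, 28, 44)

    def test_naive_liver_stratum(self, fixture_cohort):
        patients, _ = fixture_cohort
        r = pharmacotyping_efficacy(
            patients,
            lambda df: (df.treatment_status == "treatment-naive")
            & (df.biopsy_site == "liver_metastasis"),
        )
        assert (r.percent, r.numerator, r.denominator) == (78.6, 11, 14)

    def test_zero_successes(self):
        df = pd.DataFrame({
            "histology_confirmed_pc": [True, True],
            "pharmacotyped": [False, False],
        })
        assert pharmacotyping_efficacy(df).percent == 0.0

    def test_empty_stratum_rejected(self, fixture_cohort):
        patients, _ = fixture_cohort
        with pytest.raises(CohortError):
            pharmacotyping_efficacy(patients, lambda df: df.biopsy_site == "lung")

    def test_order_invariance(self, fixture_cohort):
        patients, _ = fixture_cohort
        shuffled = patients.sample(frac=1, random_state=0)
        assert pharmacotyping_efficacy(shuffled) == pharmacotyping_efficacy(patients)


class TestAccuracy:
    def test_all_match_is_100(self):
        ev = pd.DataFrame({
            "therapy_line": [1, 1],
            "treatment_status": ["treatment-naive"] * 2,
            "predicted_call": ["sensitive", "resistant"],
            "best_response": ["PR", "PD"],
        })
        r = prediction_accuracy(ev)
        assert (r.percent, r.matches, r.evaluated) == (100.0, 2, 2)

    def test_not_available_excluded_and_counted(self):
        ev = pd.DataFrame({
            "therapy_line": [1, 1, 1],
            "treatment_status": ["treatment-naive"] * 3,
            "predicted_call": ["sensitive", "sensitive", "resistant"],
            "best_response": ["SD", "not_available", "SD"],
        })
        r = prediction_accuracy(ev)
        assert r.evaluated == 2
        assert r.excluded_not_available == 1
        assert r.percent == 50.0

    def test_no_evaluable_rejected(self):
        ev = pd.DataFrame({
            "therapy_line": [1],
            "treatment_status": ["pretreated"],
            "predicted_call": ["sensitive"],
            "best_response": ["not_available"],
        })
        with pytest.raises(CohortError):
            prediction_accuracy(ev)

    def test_fixture_strata(self, fixture_cohort):
        _, evaluations = fixture_cohort
        second = prediction_accuracy(evaluations, therapy_line=2,
                                     treatment_status="treatment-naive")
        assert (second.percent, second.matches, second.evaluated) == (80.0, 4, 5)
        pre = prediction_accuracy(evaluations, treatment_status="pretreated")
        assert (pre.percent, pre.matches, pre.evaluated) == (40.0, 2, 5)


class TestFisher:
    def test_printed_table_liver(self):
        assert round(fisher_exact_two_sided([[11, 3], [9, 5]]), 4) == 0.6776

    def test_printed_table_site(self):
        assert round(fisher_exact_two_sided([[11, 3], [8, 8]]), 4) == 0.1424

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(CohortError):
            fisher_exact_two_sided([[0, 0], [0, 0]])

    def test_negative_rejected(self):
        with pytest.raises(CohortError):
            fisher_exact_two_sided([[1, -1], [2, 3]])

    @given(st.tuples(st.integers(0, 60), st.integers(0, 60),
                     st.integers(0, 60), st.integers(0, 60)))
    @settings(max_examples=200)
    def test_matches_scipy_oracle(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        ours = fisher_exact_two_sided([[a, b], [c, d]])
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert ours == pytest.approx(p, rel=1e-8, abs=1e-12)
        assert 0.0 < ours <= 1.0 + 1e-12

    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30)))
    @settings(max_examples=100)
    def test_symmetry_under_row_and_column_swap(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert fisher_exact_two_sided([[c, d], [a, b]]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_two_sided([[b, a], [d, c]]) == pytest.approx(p, rel=1e-12)


def mw_enumeration_oracle(x, y):
    """Independent exact two-sided Mann-Whitney by pair counting over all
    label assignments of the pooled sample."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in xs for yi in ys
        )

    u_obs = u_of(set(range(nx)))
    us = [u_of(set(s)) for s in combinations(range(len(pooled)), nx)]
    lo = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2.0 * min(lo, hi))


class TestMannWhitney:
    def test_identical_samples(self):
        assert mann_whitney_two_sided([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_small_case_is_one_third(self):
        assert mann_whitney_two_sided([1, 2], [10, 20]) == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(CohortError):
            mann_whitney_two_sided([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, 9).astype(float)
        y = rng.integers(0, 20, 5).astype(float)
        assert mann_whitney_two_sided(x, y) == pytest.approx(
            mw_enumeration_oracle(x, y), abs=1e-12
        )

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        ours = mann_whitney_two_sided(x, y)
        ref = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)


class TestKaplanMeier:
    def test_all_events_median(self):
        c = km_curve([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert c.median_days == 3  # S(3) = 0.4 <= 0.5
        assert c.survival_probabilities == pytest.approx([0.8, 0.6, 0.4, 0.2, 0.0])

    def test_worked_censored_example(self):
        # censored 1, events 2 and 3, censored 4, event 5
        c = km_curve([1, 2, 3, 4, 5], [0, 1, 1, 0, 1])
        assert c.survival_at(2) == pytest.approx(0.75)  # 3/4
        assert c.survival_at(3) == pytest.approx(0.50)  # 3/4 * 2/3
        assert c.median_days == 3

    def test_all_censored(self):
        c = km_curve([5, 6, 7], [0, 0, 0])
        assert c.event_times == ()
        assert c.median_days is None
        assert c.survival_at(100) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(CohortError):
            km_curve([-1, 2], [1, 1])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 50, 40).astype(float)
        c = km_curve(t, np.ones(40, dtype=int))
        for et, sp in zip(c.event_times, c.survival_probabilities):
            assert sp == pytest.approx(np.mean(t > et))

    def test_curve_non_increasing_and_at_risk_decreasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(30, 50)
        e = rng.integers(0, 2, 50)
        if e.sum() == 0:
            e[0] = 1
        c = km_curve(t, e)
        assert all(b <= a + 1e-12 for a, b in
                   zip(c.survival_probabilities, c.survival_probabilities[1:]))
        assert all(b < a for a, b in zip(c.at_risk, c.at_risk[1:]))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        t = rng.exponential(50, 60).round() + 1
        e = rng.integers(0, 2, 60)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        c = km_curve(t, e)
        for et, sp in zip(c.event_times, c.survival_probabilities):
            assert sp == pytest.approx(float(kmf.survival_function_at_times(et).iloc[0]))


class TestLogrank:
    def test_identical_groups_p_one(self):
        chi2, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_separated_groups(self):
        # events A={1,2,3}, B={101,102,103}; walking the 6 event times:
        # O-E = (1-3/6)+(1-2/5)+(1-1/4) = 1.85
        # V = (3/6)(3/6) + (2/5)(3/5) + (1/4)(3/4) = 0.6775
        chi2, p = logrank_test([1, 2, 3], [1, 1, 1], [101, 102, 103], [1, 1, 1])
        assert chi2 == pytest.approx(1.85**2 / 0.6775, rel=1e-12)
        assert p == pytest.approx(scipy.stats.chi2.sf(1.85**2 / 0.6775, 1), rel=1e-12)

    def test_zero_event_group_warns(self):
        with pytest.warns(UserWarning, match="zero events"):
            logrank_test([1, 2], [1, 1], [5, 6], [0, 0])

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(30, 20), rng.exponential(60, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2)
        assert p1 == pytest.approx(p2)

    def test_matches_lifelines(self):
        stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(30, 30).round() + 1, rng.exponential(70, 30).round() + 1
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        if ea.sum() == 0:
            ea[0] = 1
        if eb.sum() == 0:
            eb[0] = 1
        ours_chi2, ours_p = logrank_test(ta, ea, tb, eb)
        ref = stats.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours_chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours_p == pytest.approx(ref.p_value, rel=1e-9)


class TestSubtypeConcordance:
    def test_fixture_concordance(self, fixture_cohort):
        patients, _ = fixture_cohort
        r = subtype_concordance(patients)
        assert (r.percent, r.agreements, r.evaluable) == (76.2, 16, 21)
        assert (r.pdo_classical_percent, r.pdo_classical, r.pdo_known) == (76.0, 19, 25)
        assert (r.tissue_classical_percent, r.tissue_classical, r.tissue_known) == (85.7, 18, 21)

    def test_perfect_agreement(self):
        df = pd.DataFrame({
            "pdo_subtype": ["classical", "basal_like"],
            "tissue_subtype": ["classical", "basal_like"],
        })
        assert subtype_concordance(df).percent == 100.0

    def test_no_pairs_rejected(self):
        df = pd.DataFrame({"pdo_subtype": ["classical"], "tissue_subtype": ["unknown"]})
        with pytest.raises(CohortError):
            subtype_concordance(df)
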