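"""Risk stratification: cutoff, classification, odds ratio, KM, Welch."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from nwistrat.errors import (DegenerateTableError, DomainError, InputError,
                             InsufficientDataError, JoinError)
from nwistrat.risk import (ContingencyTable, build_contingency, classify,
                           compare_groups_from_summary, derive_cutoff,
                           derive_cutoff_from_summary, event_summary,
                           km_event_free, odds_ratio, stratify_cohort)
from nwistrat.simulate import CohortConfig, generate_cohort


class TestDeriveCutoff:
    def test_summary_cutoff_is_mean_plus_sd(self):
        cut = derive_cutoff_from_summary(2900.0, 1200.0)
        assert cut.cutoff == 4100.0

    def test_hand_values(self):
        cut = derive_cutoff([2.0, 4.0, 6.0])
        assert cut.reference_mean == 4.0
        assert cut.reference_sd == pytest.approx(2.0)
        assert cut.cutoff == pytest.approx(6.0)

    def test_identical_values(self):
        assert derive_cutoff([5.0, 5.0, 5.0]).cutoff == 5.0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            derive_cutoff([1.0])

    @given(st.floats(-1000, 1000))
    def test_translation_equivariance(self, k):
        base = derive_cutoff([2.0, 4.0, 6.0]).cutoff
        shifted = derive_cutoff([2.0 + k, 4.0 + k, 6.0 + k]).cutoff
        assert shifted == pytest.approx(base + k, abs=1e-6)


class TestClassify:
    cutoff = derive_cutoff_from_summary(2900.0, 1200.0)

    @pytest.mark.parametrize("w1,expected", [
        (2900.0, "high_risk"),   # decompensated-class mean
        (4100.0, "low_risk"),    # exactly at the threshold: "or more"
        (6400.0, "low_risk"),    # event-free-class mean
    ])
    def test_boundary_rule(self, w1, expected):
        assert classify(w1, self.cutoff) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify(-1.0, self.cutoff)

    @given(st.floats(0, 10000), st.floats(0, 10000))
    def test_monotone(self, w_lo, w_hi):
        lo, hi = sorted((w_lo, w_hi))
        if classify(lo, self.cutoff) == "low_risk":
            assert classify(hi, self.cutoff) == "low_risk"


class TestContingency:
    def test_one_per_cell(self):
        tab = build_contingency(["low_risk", "high_risk", "low_risk", "high_risk"],
                                [False, False, True, True])
        assert (tab.a, tab.b, tab.c, tab.d) == (1, 1, 1, 1)

    def test_all_low_no_events(self):
        tab = build_contingency(["low_risk"] * 7, [False] * 7)
        assert (tab.a, tab.b, tab.c, tab.d) == (7, 0, 0, 0)

    def test_planted_cells(self):
        classes = (["low_risk"] * 96 + ["high_risk"] * 11 +
                   ["low_risk"] * 7 + ["high_risk"] * 37)
        events = [False] * 107 + [True] * 44
        tab = build_contingency(classes, events)
        assert (tab.a, tab.b, tab.c, tab.d) == (96, 11, 7, 37)
        assert tab.total == 151

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            build_contingency(["low_risk"], [True, False])


class TestOddsRatio:
    def test_balanced_table(self):
        res = odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert math.log(res.ci_low) == pytest.approx(-math.log(res.ci_high))

    def test_hand_arithmetic(self):
        res = odds_ratio(ContingencyTable(96, 11, 7, 37))
        assert res.odds_ratio == pytest.approx(96 * 37 / (11 * 7), rel=1e-12)
        assert res.odds_ratio == pytest.approx(46.13, abs=0.01)
        assert not res.corrected
        assert res.p_value < 0.001

    def test_haldane_correction(self):
        res = odds_ratio(ContingencyTable(10, 0, 5, 5))
        assert res.corrected
        assert res.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5), rel=1e-12)
        assert res.odds_ratio == pytest.approx(21.0)

    def test_zero_cell_without_correction(self):
        with pytest.raises(DegenerateTableError):
            odds_ratio(ContingencyTable(10, 0, 5, 5), correction=False)

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_transpose_and_row_swap(self, cells):
        a, b, c, d = cells
        base = odds_ratio(ContingencyTable(a, b, c, d))
        transposed = odds_ratio(ContingencyTable(a, c, b, d))
        assert transposed.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-12)
        swapped = odds_ratio(ContingencyTable(b, a, d, c))
        assert swapped.odds_ratio == pytest.approx(1 / base.odds_ratio, rel=1e-12)
        assert swapped.ci_low == pytest.approx(1 / base.ci_high, rel=1e-9)

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_matches_statsmodels_woolf(self, cells):
        """Independent cross-check against statsmodels Table2x2."""
        sm = pytest.importorskip("statsmodels.api")
        a, b, c, d = cells
        res = odds_ratio(ContingencyTable(a, b, c, d))
        # statsmodels' layout: rows = exposure, cols = outcome
        t22 = sm.stats.Table2x2(np.array([[a, c], [b, d]]))
        assert res.odds_ratio == pytest.approx(1 / t22.oddsratio, rel=1e-9) or \
            res.odds_ratio == pytest.approx(t22.oddsratio, rel=1e-9)
        lo, hi = t22.oddsratio_confint()
        width_sm = math.log(hi) - math.log(lo)
        width_us = math.log(res.ci_high) - math.log(res.ci_low)
        assert width_us == pytest.approx(width_sm, rel=1e-9)


class TestKaplanMeier:
    def test_no_events_flat(self):
        curve = km_event_free([5.0, 10.0, 20.0], [False, False, False])
        assert len(curve.times) == 0

    def test_hand_product_limit(self):
        """times [1,2,3], events [1,1,0]: S = 2/3 after t=1, 1/3 after t=2."""
        curve = km_event_free([1.0, 2.0, 3.0], [True, True, False])
        np.testing.assert_array_equal(curve.times, [1.0, 2.0])
        np.testing.assert_array_equal(curve.n_at_risk, [3, 2])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])
        assert curve.at(2.5) == pytest.approx(1 / 3)
        assert curve.at(0.5) == 1.0

    @given(st.lists(st.integers(1, 40), min_size=1, max_size=15))
    def test_no_censoring_matches_ecdf(self, months):
        """With no censoring KM reduces to 1 - empirical CDF."""
        times = [float(m) for m in months]
        curve = km_event_free(times, [True] * len(times))
        arr = np.array(times)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(arr > t), abs=1e-9)

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(4)
        times = rng.uniform(1, 40, 60)
        events = rng.random(60) < 0.5
        curve = km_event_free(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            km_event_free([-1.0, 2.0], [True, False])


class TestWelchFromSummary:
    def test_identical_groups(self):
        res = compare_groups_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_study_group_summaries_significant(self):
        res = compare_groups_from_summary(5400, 3500, 151, 2900, 1200, 11)
        assert res.p_two_sided < 0.001

    def test_matches_sample_level_welch(self):
        """Summary-level Welch equals scipy's on samples with those moments."""
        rng = np.random.default_rng(8)
        a = rng.normal(size=23)
        a = (a - a.mean()) / a.std(ddof=1) * 3.0 + 10.0
        b = rng.normal(size=17)
        b = (b - b.mean()) / b.std(ddof=1) * 5.0 + 7.0
        direct = stats.ttest_ind(a, b, equal_var=False)
        summary = compare_groups_from_summary(10.0, 3.0, 23, 7.0, 5.0, 17)
        assert summary.t_statistic == pytest.approx(direct.statistic, rel=1e-9)
        assert summary.p_two_sided == pytest.approx(direct.pvalue, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups_from_summary(5.0, 1.0, 1, 4.0, 1.0, 10)


def _planted_cohort():
    """151 patients with planted W1 values and the 15/10/19 event mix."""
    rows = []
    for i in range(151):
        if i < 107:
            event, etype, w1 = False, "none", 6400.0
        else:
            j = i - 107
            etype = "death" if j < 15 else ("vad" if j < 25 else "htx")
            event, w1 = True, 2900.0
        rows.append({"patient_id": f"P{i:03d}", "event": int(event),
                     "event_type": etype, "followup_months": 12.0 + i % 20,
                     "w1": w1})
    frame = pd.DataFrame(rows)
    results = frame[["patient_id", "w1"]]
    outcomes = frame.drop(columns="w1")
    return results, outcomes


class TestStratifyCohort:
    def test_event_accounting(self):
        """15 deaths, 10 VAD, 19 HTx in 151 -> 9.9% / 6.6% / 12.6%."""
        results, outcomes = _planted_cohort()
        report = stratify_cohort(results, outcomes, 4100.0)
        assert report.events["percentages"] == {"death": 9.9, "vad": 6.6,
                                                "htx": 12.6}
        assert report.events["total_events"] == 44
        assert report.events["event_free_n"] == 107

    def test_percentages_sum_to_total_fraction(self):
        results, outcomes = _planted_cohort()
        report = stratify_cohort(results, outcomes, 4100.0)
        total = sum(report.events["counts"].values())
        assert total / report.n_patients == pytest.approx(44 / 151)

    def test_zero_event_cohort(self):
        results, outcomes = _planted_cohort()
        outcomes = outcomes.assign(event=0, event_type="none")
        report = stratify_cohort(results, outcomes, 4100.0)
        assert report.odds_ratio.corrected
        assert len(report.km_all.times) == 0

    def test_unmatched_ids_rejected(self):
        results, outcomes = _planted_cohort()
        outcomes = outcomes.iloc[:-1]
        with pytest.raises(JoinError):
            stratify_cohort(results, outcomes, 4100.0)

    def test_high_risk_curve_dominated(self):
        """High-risk stratum survival never exceeds low-risk survival."""
        cfg = CohortConfig(60, 20, seed=13)
        patients = generate_cohort(cfg, include_waveforms=False)
        results = pd.DataFrame([{"patient_id": p.patient_id, "w1": p.w1_true}
                                for p in patients])
        outcomes = pd.DataFrame([{"patient_id": p.patient_id,
                                  "event": int(p.event),
                                  "event_type": p.event_type,
                                  "followup_months": p.followup_months}
                                 for p in patients])
        report = stratify_cohort(results, outcomes, 4100.0)
        grid = np.linspace(0.0, 45.0, 50)
        for t in grid:
            assert report.km_high_risk.at(t) <= report.km_low_risk.at(t) + 1e-12


class TestEventSummary:
    def test_counts_and_percentages(self):
        types = ["death"] * 15 + ["vad"] * 10 + ["htx"] * 19 + ["none"] * 107
        summary = event_summary(types)
        assert summary["counts"] == {"death": 15, "vad": 10, "htx": 19}
        assert summary["percentages"]["death"] == 9.9
        assert summary["total_events"] == 44
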