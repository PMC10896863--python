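from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from artgaps.data_model import AnalysisConfig
from artgaps.exposure import DayCalendar, day_calendar_from_days
from artgaps.outcomes import (CATEGORY_INTERMEDIATE, CATEGORY_LOW, CATEGORY_OPTIMAL,
                              classify_adherence, compute_outcome, compute_pdc,
                              detect_discontinuation, find_gap_runs, gap_bin_label,
                              gap_bin_labels, outcomes_frame, summarize_cohort,
                              summarize_gaps)


def calendar_with(covered: int, facility: int = 0, window: int = 365) -> DayCalendar:
    s = "C" * covered + "F" * facility + "G" * (window - covered - facility)
    return DayCalendar.from_string(s, "X")


class TestPDC:
    def test_worked_example_292_of_365(self):
        covered, eligible, pdc = compute_pdc(calendar_with(292))
        assert (covered, eligible) == (292, 365)
        assert pdc == Fraction(292, 365)
        assert round(float(pdc), 2) == 0.80

    def test_full_coverage(self):
        assert compute_pdc(calendar_with(365))[2] == 1

    def test_facility_days_removed_from_denominator(self):
        covered, eligible, pdc = compute_pdc(calendar_with(292, facility=65))
        assert (covered, eligible) == (292, 300)
        assert pdc == Fraction(292, 300)

    def test_all_facility_undefined(self):
        covered, eligible, pdc = compute_pdc(calendar_with(0, facility=365))
        assert eligible == 0 and pdc is None


class TestClassification:
    def test_exact_boundary_is_optimal(self, config):
        flags, cat = classify_adherence(Fraction(95, 100), config)
        assert cat == CATEGORY_OPTIMAL and flags[0.95]

    def test_no_rounding_before_comparison(self, config):
        # 347/365 ~ 0.9507 is optimal; 346/365 ~ 0.9479 is not
        assert classify_adherence(Fraction(347, 365), config)[1] == CATEGORY_OPTIMAL
        flags, cat = classify_adherence(Fraction(346, 365), config)
        assert cat == CATEGORY_INTERMEDIATE and not flags[0.95] and flags[0.90]

    def test_low_category_flags(self, config):
        flags, cat = classify_adherence(Fraction(69, 100), config)
        assert cat == CATEGORY_LOW and not any(flags.values())


class TestGapRuns:
    def test_fully_covered_no_runs(self):
        assert find_gap_runs(calendar_with(365)) == []

    def test_single_gap_run(self):
        cal = day_calendar_from_days([(1, "A", 30), (61, "A", 305)], [], 365)
        (run,) = find_gap_runs(cal)
        assert (run.start_day, run.end_day, run.length) == (31, 60, 30)

    def test_bridge_vs_split_policies(self):
        # covered 1-30, gap 31-40, facility 41-45, gap 46-60, covered 61-365
        s = "C" * 30 + "G" * 10 + "F" * 5 + "G" * 15 + "C" * 305
        cal = DayCalendar.from_string(s)
        (bridged,) = find_gap_runs(cal, "bridge")
        assert (bridged.start_day, bridged.end_day, bridged.length) == (31, 60, 25)
        split = find_gap_runs(cal, "split")
        assert [(r.start_day, r.length) for r in split] == [(31, 10), (46, 15)]

    def test_pure_facility_stretch_is_not_a_gap(self):
        cal = DayCalendar.from_string("C" * 10 + "F" * 5 + "C" * 350)
        assert find_gap_runs(cal) == []

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            find_gap_runs(calendar_with(365), "merge")


class TestGapBins:
    @pytest.mark.parametrize("length,label", [
        (0, "0 days (no gap)"), (1, "1 to 6 days"), (6, "1 to 6 days"),
        (7, "7 to <14 days"), (13, "7 to <14 days"), (14, "14 to <30 days"),
        (29, "14 to <30 days"), (30, "30 to <90 days"), (89, "30 to <90 days"),
        (90, "90 to <120 days"), (119, "90 to <120 days"), (120, "120 to <150 days"),
        (150, "150 to <180 days"), (179, "150 to <180 days"), (180, ">=180 days"),
        (335, ">=180 days"),
    ])
    def test_eight_duration_bins_plus_no_gap(self, length, label, config):
        assert gap_bin_label(length, config.gap_bins) == label

    def test_label_list_covers_all_bins(self, config):
        assert len(gap_bin_labels(config.gap_bins)) == 9


class TestDiscontinuation:
    def test_89_day_gap_is_not_discontinuation(self, config):
        cal = DayCalendar.from_string("C" * 30 + "G" * 89 + "C" * 246)
        disc, t = detect_discontinuation(find_gap_runs(cal), config)
        assert (disc, t) == (False, None)

    def test_never_refilled_index_supply(self, config):
        """30-day index supply, never refilled: gap starts day 31, time 30."""
        cal = day_calendar_from_days([(1, "A", 30)], [], 365)
        runs = find_gap_runs(cal)
        assert runs[0].length == 335
        disc, t = detect_discontinuation(runs, config)
        assert disc and t == 30

    def test_first_qualifying_run_sets_time(self, config):
        s = "C" * 100 + "G" * 90 + "C" * 39 + "G" * 120 + "C" * 16
        runs = find_gap_runs(DayCalendar.from_string(s))
        assert [(r.start_day, r.length) for r in runs] == [(101, 90), (230, 120)]
        disc, t = detect_discontinuation(runs, config)
        assert disc and t == 100

    def test_time_bounds(self, config):
        # latest possible qualifying start: day 276 -> time 275
        cal = DayCalendar.from_string("C" * 275 + "G" * 90)
        disc, t = detect_discontinuation(find_gap_runs(cal), config)
        assert disc and t == 275


class TestSummaries:
    def test_single_perfect_beneficiary(self, config):
        out = outcomes_frame([calendar_with(365)], config)
        cohort = pd.DataFrame([{"beneficiary_id": "X", "anchor_class": "INSTI",
                                "str_flag": "STR"}])
        table = summarize_cohort(out, cohort, config)
        assert table.loc["PDC mean", "Overall"] == 1.0
        assert table.loc["PDC >= 0.95 %", "Overall"] == 100.0
        assert table.loc["Discontinuation %", "Overall"] == 0.0

    def test_mean_and_categories(self, config):
        cal80 = calendar_with(292)
        cal80.beneficiary_id = "Y"
        out = outcomes_frame([calendar_with(365), cal80], config)
        cohort = pd.DataFrame([
            {"beneficiary_id": "X", "anchor_class": "INSTI", "str_flag": "STR"},
            {"beneficiary_id": "Y", "anchor_class": "PI", "str_flag": "MTR"}])
        table = summarize_cohort(out, cohort, config)
        assert table.loc["PDC mean", "Overall"] == pytest.approx(0.90)
        assert table.loc["PDC >= 0.95 n", "Overall"] == 1
        assert table.loc["PDC 0.70 to < 0.95 n", "Overall"] == 1

    def test_categories_partition_cohort(self, config, small_bundle):
        from artgaps.cohort import apply_selection, identify_index_events
        from artgaps.exposure import calendars_for_cohort
        cohort, _ = apply_selection(identify_index_events(small_bundle, config),
                                    small_bundle, config)
        out = outcomes_frame(calendars_for_cohort(small_bundle, cohort, config).values(),
                             config)
        table = summarize_cohort(out, cohort, config)
        for stratum in table.columns:
            parts = sum(table.loc[f"{lbl} n", stratum] for lbl in
                        ("PDC < 0.70", "PDC 0.70 to < 0.95", "PDC >= 0.95"))
            assert parts == table.loc["N", stratum]
            bins = sum(table.loc[f"Longest gap {lbl} n", stratum]
                       for lbl in gap_bin_labels(config.gap_bins))
            assert bins == table.loc["N", stratum]


day_string = st.text(alphabet="CFG", min_size=30, max_size=365)


class TestOutcomeProperties:
    @given(s=day_string)
    def test_discontinued_iff_longest_gap_reaches_threshold(self, s, config):
        o = compute_outcome(DayCalendar.from_string(s), config)
        assert o.discontinued == (o.longest_gap >= config.discontinuation_gap_days)

    @given(s=st.text(alphabet="CG", min_size=365, max_size=365))
    def test_optimal_without_facility_days_implies_persistence(self, s, config):
        o = compute_outcome(DayCalendar.from_string(s), config)
        if o.pdc is not None and o.pdc >= Fraction(95, 100):
            assert not o.discontinued and o.longest_gap <= 18

    @given(s=day_string)
    def test_threshold_flags_non_increasing(self, s, config):
        o = compute_outcome(DayCalendar.from_string(s), config)
        if o.pdc is not None:
            flags = [o.threshold_flags[t] for t in config.adherence_thresholds]
            assert flags == sorted(flags, reverse=True)
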