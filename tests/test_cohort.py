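import datetime as dt

import pandas as pd
import pytest

from artgaps.cohort import apply_selection, has_hiv_diagnosis, identify_index_events
from artgaps.data_model import parse_months, format_months

from conftest import make_beneficiary, toy_bundle

IDX = dt.date(2015, 6, 1)


def monthly(bid, drug, start, n, supply=30):
    return [(bid, pd.Timestamp(start) + pd.Timedelta(days=30 * k), drug, supply)
            for k in range(n)]


class TestIdentifyIndexEvents:
    def test_first_ever_insti_fill_is_naive_initiation(self, config):
        b = toy_bundle([make_beneficiary("P1", IDX, config)],
                       monthly("P1", "INSTI_A", IDX, 12), config)
        events = identify_index_events(b, config)
        row = events.iloc[0]
        assert len(events) == 1
        assert row.index_date.date() == IDX and row.index_drug_id == "INSTI_A"
        assert row.anchor_class == "INSTI" and not row.treatment_experienced

    def test_continuous_user_has_no_index_event(self, config):
        fills = monthly("P1", "PI_A", dt.date(2013, 6, 1), 36)
        b = toy_bundle([make_beneficiary("P1", IDX, config)], fills, config)
        assert len(identify_index_events(b, config)) == 0

    def test_switcher_is_treatment_experienced(self, config):
        fills = monthly("P1", "PI_A", dt.date(2013, 6, 1), 25)  # through ~2015-05
        fills += monthly("P1", "INSTI_A", IDX, 12)
        b = toy_bundle([make_beneficiary("P1", IDX, config)], fills, config)
        events = identify_index_events(b, config)
        row = events.iloc[0]
        assert row.index_drug_id == "INSTI_A" and row.index_date.date() == IDX
        assert row.treatment_experienced

    def test_earliest_qualifying_initiation_wins(self, config):
        fills = monthly("P1", "NNRTI_A", dt.date(2014, 3, 1), 3)
        fills += monthly("P1", "INSTI_A", IDX, 3)
        b = toy_bundle([make_beneficiary("P1", dt.date(2014, 3, 1), config)], fills, config)
        assert identify_index_events(b, config).iloc[0].index_drug_id == "NNRTI_A"

    def test_non_anchor_fills_ignored(self, config):
        b = toy_bundle([make_beneficiary("P1", IDX, config)],
                       monthly("P1", "STATIN", IDX, 12), config)
        assert len(identify_index_events(b, config)) == 0

    def test_refill_after_long_break_counts_as_new(self, config):
        fills = [("P1", pd.Timestamp("2013-01-10"), "INSTI_A", 30)]
        fills += monthly("P1", "INSTI_A", IDX, 12)  # > 365-day same-drug break
        b = toy_bundle([make_beneficiary("P1", IDX, config)], fills, config)
        row = identify_index_events(b, config).iloc[0]
        assert row.index_date.date() == IDX


class TestHIVDiagnosis:
    @pytest.mark.parametrize("code,system,expected", [
        ("B20", "ICD10CM", True),
        ("b20", "ICD10CM", True),
        ("B97.35", "ICD10CM", True),
        ("0420", "ICD9CM", False),   # not an exact listed code
        ("042", "ICD9CM", True),
        ("079.53", "ICD9CM", True),
        ("Z99", "ICD10CM", False),
    ])
    def test_code_matching(self, config, code, system, expected):
        b = toy_bundle([make_beneficiary("P1", IDX, config)],
                       monthly("P1", "INSTI_A", IDX, 2), config,
                       diagnoses=[{"beneficiary_id": "P1",
                                   "service_date": pd.Timestamp("2015-01-15"),
                                   "code": code, "code_system": system,
                                   "setting": "outpatient"}])
        window = (IDX - dt.timedelta(days=365), IDX - dt.timedelta(days=1))
        assert has_hiv_diagnosis(b, "P1", window, config) is expected

    def test_claim_outside_window_not_counted(self, config):
        claim_date = IDX - dt.timedelta(days=366)  # one day before window start
        b = toy_bundle([make_beneficiary("P1", IDX, config)],
                       monthly("P1", "INSTI_A", IDX, 2), config,
                       diagnoses=[{"beneficiary_id": "P1",
                                   "service_date": pd.Timestamp(claim_date),
                                   "code": "B20", "code_system": "ICD10CM",
                                   "setting": "outpatient"}])
        window = (IDX - dt.timedelta(days=365), IDX - dt.timedelta(days=1))
        assert not has_hiv_diagnosis(b, "P1", window, config)


def _dx(bid, date=pd.Timestamp("2015-01-15")):
    return {"beneficiary_id": bid, "service_date": date, "code": "B20",
            "code_system": "ICD10CM", "setting": "outpatient"}


class TestApplySelection:
    def _bundle(self, config, **overrides):
        people = [make_beneficiary("P1", IDX, config, **overrides)]
        return toy_bundle(people, monthly("P1", "INSTI_A", IDX, 12), config,
                          diagnoses=[_dx("P1")])

    def test_clean_person_retained(self, config):
        b = self._bundle(config)
        cohort, attrition = apply_selection(identify_index_events(b, config), b, config)
        assert list(cohort["beneficiary_id"]) == ["P1"]
        assert attrition["n_remaining"].tolist() == [1, 1, 1, 1, 1, 1]

    def test_death_in_followup_excluded_at_death_step(self, config):
        b = self._bundle(config, death_date=pd.Timestamp(IDX) + pd.Timedelta(days=200))
        cohort, attrition = apply_selection(identify_index_events(b, config), b, config)
        assert len(cohort) == 0
        assert attrition["n_remaining"].tolist() == [1, 1, 1, 0, 0, 0]

    def test_death_after_followup_retained(self, config):
        b = self._bundle(config, death_date=pd.Timestamp(IDX) + pd.Timedelta(days=400))
        cohort, _ = apply_selection(identify_index_events(b, config), b, config)
        assert len(cohort) == 1

    def test_enrollment_break_excluded_at_eligibility_step(self, config):
        base = make_beneficiary("P1", IDX, config)
        months = parse_months(base["enrollment_months"])
        months.discard((2015, 3))  # three months before index
        base["enrollment_months"] = format_months(months)
        b = toy_bundle([base], monthly("P1", "INSTI_A", IDX, 12), config,
                       diagnoses=[_dx("P1")])
        cohort, attrition = apply_selection(identify_index_events(b, config), b, config)
        assert len(cohort) == 0
        assert attrition["n_remaining"].tolist() == [1, 0, 0, 0, 0, 0]

    def test_no_hiv_diagnosis_excluded(self, config):
        b = toy_bundle([make_beneficiary("P1", IDX, config)],
                       monthly("P1", "INSTI_A", IDX, 12), config,
                       diagnoses=[_dx("P1", pd.Timestamp(IDX))])  # on index day, not pre
        _, attrition = apply_selection(identify_index_events(b, config), b, config)
        assert attrition["n_remaining"].tolist() == [1, 1, 0, 0, 0, 0]

    def test_missing_county_excluded(self, config):
        b = self._bundle(config, county_code=None)
        _, attrition = apply_selection(identify_index_events(b, config), b, config)
        assert attrition["n_remaining"].tolist() == [1, 1, 1, 1, 0, 0]

    def test_dual_anchor_index_excluded_last(self, config):
        fills = monthly("P1", "INSTI_A", IDX, 12) + [("P1", pd.Timestamp(IDX), "PI_A", 30)]
        b = toy_bundle([make_beneficiary("P1", IDX, config)], fills, config,
                       diagnoses=[_dx("P1")])
        events = identify_index_events(b, config)
        assert events.iloc[0].n_index_anchors == 2
        _, attrition = apply_selection(events, b, config)
        assert attrition["n_remaining"].tolist() == [1, 1, 1, 1, 1, 0]

    def test_same_day_non_anchor_fill_is_not_dual_anchor(self, config):
        fills = monthly("P1", "INSTI_A", IDX, 12) + [("P1", pd.Timestamp(IDX), "STATIN", 30)]
        b = toy_bundle([make_beneficiary("P1", IDX, config)], fills, config,
                       diagnoses=[_dx("P1")])
        cohort, _ = apply_selection(identify_index_events(b, config), b, config)
        assert len(cohort) == 1

    def test_attrition_monotone_and_order_stable(self, config, small_bundle):
        events = identify_index_events(small_bundle, config)
        cohort, attrition = apply_selection(events, small_bundle, config)
        n = attrition["n_remaining"].tolist()
        assert n == sorted(n, reverse=True)
        shuffled = small_bundle.copy()
        shuffled.prescriptions = shuffled.prescriptions.sample(
            frac=1.0, random_state=4).reset_index(drop=True)
        cohort2, _ = apply_selection(identify_index_events(shuffled, config),
                                     shuffled, config)
        assert set(cohort2["beneficiary_id"]) == set(cohort["beneficiary_id"])
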