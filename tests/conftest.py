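import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from artgaps.data_model import AnalysisConfig, ClaimsBundle, format_months, months_touching

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_bundle(config):
    from artgaps.synthetic_claims import SimulationParams, generate_bundle
    return generate_bundle(SimulationParams(n_beneficiaries=60, seed=11), config)


def make_beneficiary(bid: str, index_date: dt.date, config: AnalysisConfig,
                     **overrides) -> dict:
    """A cohort-eligible beneficiary row with enrollment spanning the study period."""
    months = months_touching(index_date - dt.timedelta(days=config.pre_period_days + 30),
                             index_date + dt.timedelta(days=config.followup_days + 30))
    row = {
        "beneficiary_id": bid, "birth_date": pd.Timestamp("1958-04-01"),
        "sex": "male", "race_ethnicity": "White", "lis_status": "full",
        "eligibility_reason": "disability", "census_region": "South",
        "metro": "urban", "plan_type": "other", "county_code": "01001",
        "hcc_score": 1.0, "rx_per_month_pre": 5.0, "death_date": pd.NaT,
        "enrollment_months": format_months(months),
        "cm_mental_health": 0, "cm_substance_use": 0,
    }
    row.update(overrides)
    return row


TOY_CATALOG = pd.DataFrame([
    {"drug_id": "INSTI_A", "anchor_class": "INSTI", "str_flag": "STR"},
    {"drug_id": "INSTI_B", "anchor_class": "INSTI", "str_flag": "MTR"},
    {"drug_id": "PI_A", "anchor_class": "PI", "str_flag": "MTR"},
    {"drug_id": "NNRTI_A", "anchor_class": "NNRTI", "str_flag": "STR"},
    {"drug_id": "STATIN", "anchor_class": "non_anchor", "str_flag": "not_applicable"},
])


def toy_bundle(beneficiaries: list[dict], fills: list[tuple], config: AnalysisConfig,
               diagnoses: list[dict] | None = None,
               stays: list[dict] | None = None) -> ClaimsBundle:
    """Hand-constructed bundle; fills are (bid, date, drug_id, days_supply)."""
    bene = pd.DataFrame(beneficiaries)
    rx = pd.DataFrame(
        [{"beneficiary_id": b, "fill_date": pd.Timestamp(d), "drug_id": g,
          "days_supply": s, "quantity": float(s)} for b, d, g, s in fills],
        columns=["beneficiary_id", "fill_date", "drug_id", "days_supply", "quantity"])
    if diagnoses is None:
        diagnoses = [{"beneficiary_id": r["beneficiary_id"],
                      "service_date": pd.Timestamp("2014-01-15"), "code": "B20",
                      "code_system": "ICD10CM", "setting": "outpatient"}
                     for r in beneficiaries]
    dx = pd.DataFrame(diagnoses, columns=["beneficiary_id", "service_date", "code",
                                          "code_system", "setting"])
    st = pd.DataFrame(stays or [], columns=["beneficiary_id", "admit_date",
                                            "discharge_date", "setting"])
    return ClaimsBundle(beneficiaries=bene, prescriptions=rx, stays=st,
                        diagnoses=dx, drug_catalog=TOY_CATALOG.copy())
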