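"""New-user cohort selection and attrition accounting.

Identifies index events — the first in-window fill of an anchor
antiretroviral the person has not filled during the preceding washout
period — and applies the sample-selection criteria in order:

1. new anchor initiation inside the index window;
2. continuous Part A/B/D fee-for-service enrollment for the 12 months
   before and after the index date (month granularity: every calendar month
   touching the period must carry the joint coverage flag);
3. at least one inpatient or outpatient HIV diagnosis claim in the
   12-month pre-index period;
then exclusions:
4. death during the 12-month post-index period;
5. missing key covariates (age, sex, county of residence);
6. more than one distinct new anchor medication started on the index date.

Treatment-experienced switchers (any *other* anchor filled in the
pre-period) are kept and flagged.  When several initiations qualify, the
earliest is the index event (standard new-user convention).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, ClaimsBundle, months_touching, normalize_code, parse_months

COHORT_COLUMNS = ["beneficiary_id", "index_date", "index_drug_id", "anchor_class",
                  "str_flag", "treatment_experienced", "n_index_anchors"]

ATTRITION_STEPS = [
    "New anchor medication initiated in index window",
    "Continuous Part A/B/D enrollment 12 months pre- and post-index",
    "HIV diagnosis in 12-month pre-index period",
    "No death in 12-month post-index period",
    "Non-missing age, sex, and county of residence",
    "Single anchor medication initiated on index date",
]


def identify_index_events(bundle: ClaimsBundle, config: AnalysisConfig) -> pd.DataFrame:
    """One index event per beneficiary with a qualifying new-anchor fill.

    A fill qualifies when it is inside the index window and the same drug
    was not filled during the preceding ``pre_period_days`` (the washout);
    the earliest qualifying fill is the index event.  When several distinct
    anchors first appear on that date, ``n_index_anchors`` counts them (the
    lexicographically first drug id is recorded) — the multi-anchor
    exclusion acts on this later.
    """
    cat = bundle.drug_catalog
    anchors = cat[cat["anchor_class"].isin(("PI", "NNRTI", "INSTI"))]
    rx = bundle.prescriptions.merge(anchors, on="drug_id")
    if len(rx) == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    rx = rx.copy()
    rx["fill_date"] = pd.to_datetime(rx["fill_date"])
    rx = rx.sort_values(["beneficiary_id", "drug_id", "fill_date"], kind="mergesort")

    prev = rx.groupby(["beneficiary_id", "drug_id"])["fill_date"].shift()
    washed = prev.isna() | ((rx["fill_date"] - prev).dt.days > config.pre_period_days)
    in_window = (rx["fill_date"] >= pd.Timestamp(config.index_window_start)) & (
        rx["fill_date"] <= pd.Timestamp(config.index_window_end))
    cand = rx[washed & in_window]
    if len(cand) == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    index_date = cand.groupby("beneficiary_id")["fill_date"].transform("min")
    on_index = cand[cand["fill_date"] == index_date]
    events = (on_index.sort_values(["beneficiary_id", "drug_id"], kind="mergesort")
              .groupby("beneficiary_id")
              .agg(index_date=("fill_date", "first"),
                   index_drug_id=("drug_id", "first"),
                   anchor_class=("anchor_class", "first"),
                   str_flag=("str_flag", "first"),
                   n_index_anchors=("drug_id", "nunique"))
              .reset_index())

    # treatment-experienced: any other anchor filled in the pre-index period
    pre = rx.merge(events[["beneficiary_id", "index_date", "index_drug_id"]],
                   on="beneficiary_id")
    days_before = (pre["index_date"] - pre["fill_date"]).dt.days
    exp = pre[(days_before >= 1) & (days_before <= config.pre_period_days)
              & (pre["drug_id"] != pre["index_drug_id"])]
    events["treatment_experienced"] = events["beneficiary_id"].isin(
        set(exp["beneficiary_id"]))
    return events[COHORT_COLUMNS].sort_values("beneficiary_id",
                                              kind="mergesort").reset_index(drop=True)


def has_hiv_diagnosis(bundle: ClaimsBundle, beneficiary_id: str,
                      window: tuple[dt.date, dt.date],
                      config: AnalysisConfig) -> bool:
    """True iff a diagnosis claim in [window) carries a listed HIV code.

    Codes are compared case-insensitively with decimal points removed,
    against the configured list for the claim's code system.
    """
    start, end = window
    dx = bundle.diagnoses
    dx = dx[dx["beneficiary_id"] == beneficiary_id]
    if len(dx) == 0:
        return False
    dates = pd.to_datetime(dx["service_date"])
    dx = dx[(dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))]
    for code, system in zip(dx["code"], dx["code_system"]):
        if normalize_code(code) in config.hiv_code_set(system):
            return True
    return False


def _hiv_positive_ids(bundle: ClaimsBundle, events: pd.DataFrame,
                      config: AnalysisConfig) -> set[str]:
    dx = bundle.diagnoses.merge(events[["beneficiary_id", "index_date"]],
                                on="beneficiary_id")
    if len(dx) == 0:
        return set()
    dx = dx.copy()
    dx["service_date"] = pd.to_datetime(dx["service_date"])
    days_before = (dx["index_date"] - dx["service_date"]).dt.days
    dx = dx[(days_before >= 1) & (days_before <= config.pre_period_days)]
    norm = dx["code"].map(normalize_code)
    hit = pd.Series(False, index=dx.index)
    for system in dx["code_system"].unique():
        codes = config.hiv_code_set(system)
        hit |= (dx["code_system"] == system) & norm.isin(codes)
    return set(dx.loc[hit, "beneficiary_id"])


def apply_selection(events: pd.DataFrame, bundle: ClaimsBundle,
                    config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion/exclusion criteria in order; return cohort + attrition.

    The attrition table records the number of beneficiaries remaining after
    each criterion, in the order listed in :data:`ATTRITION_STEPS`.
    """
    bene = bundle.beneficiaries.set_index("beneficiary_id")
    kept = events.copy()
    kept["index_date"] = pd.to_datetime(kept["index_date"])
    attrition: list[tuple[str, int]] = [(ATTRITION_STEPS[0], len(kept))]

    # continuous A/B/D enrollment, month granularity
    def enrolled(row) -> bool:
        months = parse_months(bene.at[row.beneficiary_id, "enrollment_months"])
        idx = row.index_date.date()
        start = idx - dt.timedelta(days=config.pre_period_days)
        end = idx + dt.timedelta(days=config.followup_days - 1)
        return all(m in months for m in months_touching(start, end))

    mask = np.array([enrolled(r) for r in kept.itertuples(index=False)], dtype=bool)
    kept = kept[mask]
    attrition.append((ATTRITION_STEPS[1], len(kept)))

    kept = kept[kept["beneficiary_id"].isin(_hiv_positive_ids(bundle, kept, config))]
    attrition.append((ATTRITION_STEPS[2], len(kept)))

    # exclusion: death during post-index follow-up
    death = pd.to_datetime(kept["beneficiary_id"].map(bene["death_date"]))
    days_to_death = (death - kept["index_date"]).dt.days
    kept = kept[~(death.notna() & (days_to_death >= 0)
                  & (days_to_death <= config.followup_days - 1))]
    attrition.append((ATTRITION_STEPS[3], len(kept)))

    # exclusion: missing key covariates
    birth = kept["beneficiary_id"].map(bene["birth_date"])
    sex = kept["beneficiary_id"].map(bene["sex"])
    county = kept["beneficiary_id"].map(bene["county_code"])
    missing = birth.isna() | sex.isna() | county.isna() | (county.astype(str).str.strip() == "")
    kept = kept[~missing.to_numpy()]
    attrition.append((ATTRITION_STEPS[4], len(kept)))

    # exclusion: multiple distinct new anchors started on the index date
    kept = kept[kept["n_index_anchors"] == 1]
    attrition.append((ATTRITION_STEPS[5], len(kept)))

    cohort = kept.sort_values("beneficiary_id", kind="mergesort").reset_index(drop=True)
    attrition_df = pd.DataFrame(attrition, columns=["criterion", "n_remaining"])
    return cohort, attrition_df
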