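"""Seeded generator of Medicare-like claims bundles.

The restricted nature of the source data (100% Medicare Part A/B/D research
files) means the pipeline must be exercised on synthetic claims.  The
generator emulates the structures the analysis measures:

* demographics drawn from published margins of the study population
  (age, sex, race/ethnicity, low-income subsidy, eligibility reason,
  region, metropolitan status, plan type, comorbidity prevalences);
* cycle-based refill behaviour: at each nominal supply exhaustion the
  person stops permanently (per-cycle hazard), may switch anchor agent,
  and otherwise refills early/on time (uniform in a small window before
  exhaustion) or late (geometric delay) — producing the carry-over,
  gap, and discontinuation structure the outcome stage measures;
* treatment-experienced switchers with a prior anchor filled through the
  pre-index period; hospital/SNF/hospice stays; in-follow-up deaths;
  pre-index HIV diagnosis claims; enrollment months spanning the pre and
  post periods;
* covariate-linked effects entering through the per-cycle stop hazard
  (log-odds) and the mean refill delay (log scale), so association models
  downstream can recover planted effect sizes.

One RNG stream is derived per beneficiary from (seed, index), so growing
the cohort never perturbs existing records, and identical parameters yield
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .data_model import (AnalysisConfig, ClaimsBundle, format_months,
                         months_touching, validate_bundle)

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

_AGE_BANDS = {
    "<=34": (20, 34), "35-44": (35, 44), "45-54": (45, 54), "55-64": (55, 64),
    "65-74": (65, 74), "75-84": (75, 84), ">=85": (85, 94),
}


def _normalized(probs: dict[str, float]) -> dict[str, float]:
    total = sum(probs.values())
    if total <= 0 or any(p < 0 for p in probs.values()):
        raise ValueError("probabilities must be nonnegative with positive sum")
    return {k: v / total for k, v in probs.items()}


class DemographicMix(BaseModel):
    """Marginal distributions of beneficiary characteristics.

    Defaults approximate the study population's published margins; each
    probability table is normalized on validation.
    """

    age_band_probs: dict[str, float] = {
        "<=34": 0.044, "35-44": 0.118, "45-54": 0.348, "55-64": 0.312,
        "65-74": 0.146, "75-84": 0.031, ">=85": 0.002}
    sex_probs: dict[str, float] = {"male": 0.744, "female": 0.256}
    race_probs: dict[str, float] = {
        "White": 0.475, "Black": 0.433, "Hispanic": 0.063, "Other": 0.030}
    lis_probs: dict[str, float] = {"full": 0.821, "partial": 0.021, "none": 0.158}
    eligibility_probs: dict[str, float] = {"age": 0.092, "disability": 0.898, "esrd": 0.035}
    region_probs: dict[str, float] = {
        "Northeast": 0.221, "South": 0.472, "Midwest": 0.130, "West": 0.176}
    metro_probs: dict[str, float] = {"urban": 0.907, "rural": 0.093}
    plan_probs: dict[str, float] = {"enhanced_alternative": 0.168, "other": 0.832}
    comorbidity_prev: dict[str, float] = {
        "cardiovascular": 0.705, "renal": 0.222, "liver": 0.181, "cancer": 0.083,
        "mental_health": 0.371, "substance_use": 0.305, "lung": 0.209,
        "autoimmune": 0.231, "endocrine": 0.040, "gi": 0.266}
    hcc_mean: float = 1.04
    hcc_sd: float = 0.92
    rx_per_month_mean: float = 6.10
    rx_per_month_sd: float = 4.37

    @field_validator("age_band_probs", "sex_probs", "race_probs", "lis_probs",
                     "eligibility_probs", "region_probs", "metro_probs", "plan_probs")
    @classmethod
    def _norm(cls, v: dict[str, float]) -> dict[str, float]:
        return _normalized(v)

    @field_validator("comorbidity_prev")
    @classmethod
    def _prev_ok(cls, v: dict[str, float]) -> dict[str, float]:
        if any(not 0 <= p <= 1 for p in v.values()):
            raise ValueError("comorbidity prevalences must be in [0, 1]")
        return v

    @field_validator("age_band_probs")
    @classmethod
    def _bands_known(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(_AGE_BANDS)
        if unknown:
            raise ValueError(f"unknown age bands {sorted(unknown)}")
        return v


class RefillDelayModel(BaseModel):
    """Refill timing relative to nominal supply exhaustion.

    With probability ``p_ontime`` the refill lands uniformly in
    [ontime_low, ontime_high] days of exhaustion (default [-7, 0]: up to a
    week early); otherwise the delay is geometric with the given mean
    (support >= 1 day late).
    """

    p_ontime: float = Field(0.80, ge=0, le=1)
    ontime_low: int = -7
    ontime_high: int = 0
    mean_late_delay: float = Field(7.0, ge=1)

    @model_validator(mode="after")
    def _window_ok(self) -> "RefillDelayModel":
        if self.ontime_low > self.ontime_high or self.ontime_high > 0:
            raise ValueError("ontime window must satisfy low <= high <= 0")
        return self


class StayModel(BaseModel):
    """Facility-stay process, sampled independently of refill behaviour."""

    rate_per_year: float = Field(0.4, ge=0)
    mean_duration_days: float = Field(6.0, ge=1)
    setting_probs: dict[str, float] = {"hospital": 0.70, "snf": 0.25, "hospice": 0.05}

    @field_validator("setting_probs")
    @classmethod
    def _norm(cls, v: dict[str, float]) -> dict[str, float]:
        return _normalized(v)


class CovariateEffect(BaseModel):
    """Planted effect of one binary covariate.

    ``log_or_stop`` shifts the per-cycle stop hazard on the log-odds scale;
    ``log_delay_mult`` scales the mean late-refill delay on the log scale.
    """

    log_or_stop: float = 0.0
    log_delay_mult: float = 0.0


class DrugCatalogSpec(BaseModel):
    """Agent counts per anchor class / tablet-regimen cell.

    No protease-inhibitor single-tablet products existed in the study
    window, so PIs are all multi-tablet.
    """

    n_pi: int = Field(4, ge=1)
    n_nnrti_str: int = Field(2, ge=1)
    n_nnrti_mtr: int = Field(2, ge=1)
    n_insti_str: int = Field(3, ge=1)
    n_insti_mtr: int = Field(3, ge=1)
    n_non_anchor: int = Field(5, ge=0)


class SimulationParams(BaseModel):
    """Everything the generator needs; validated before any sampling."""

    n_beneficiaries: int = Field(..., ge=1)
    seed: int = 0
    supply_days: int = Field(30, ge=8)
    discontinuation_hazard: float = Field(0.01, ge=0, le=1)
    switch_prob: float = Field(0.02, ge=0, le=1)
    refill: RefillDelayModel = RefillDelayModel()
    stays: StayModel = StayModel()
    annual_death_rate: float = Field(0.04, ge=0, le=1)
    prior_art_prob: float = Field(0.5, ge=0, le=1)
    chronic_rx_prob: float = Field(0.6, ge=0, le=1)
    missing_county_prob: float = Field(0.0, ge=0, le=1)
    anchor_choice_probs: dict[str, float] = {
        "INSTI_STR": 0.370, "INSTI_MTR": 0.303, "NNRTI_STR": 0.101,
        "NNRTI_MTR": 0.060, "PI_MTR": 0.165}
    covariate_effects: dict[str, CovariateEffect] = {}
    demographics: DemographicMix = DemographicMix()
    drug_catalog: DrugCatalogSpec = DrugCatalogSpec()

    @field_validator("anchor_choice_probs")
    @classmethod
    def _norm(cls, v: dict[str, float]) -> dict[str, float]:
        known = {"INSTI_STR", "INSTI_MTR", "NNRTI_STR", "NNRTI_MTR", "PI_MTR"}
        if set(v) - known:
            raise ValueError(f"unknown anchor cells {sorted(set(v) - known)}")
        return _normalized(v)

    @model_validator(mode="after")
    def _supply_vs_window(self) -> "SimulationParams":
        if self.refill.ontime_low <= -self.supply_days:
            raise ValueError("early-refill window must be shorter than the supply")
        return self


def build_drug_catalog(spec: DrugCatalogSpec) -> pd.DataFrame:
    """Deterministic drug catalog matching the spec's cell counts."""
    rows = []
    cells = [("PI", "MTR", spec.n_pi), ("NNRTI", "STR", spec.n_nnrti_str),
             ("NNRTI", "MTR", spec.n_nnrti_mtr), ("INSTI", "STR", spec.n_insti_str),
             ("INSTI", "MTR", spec.n_insti_mtr)]
    for cls, flag, n in cells:
        for k in range(1, n + 1):
            rows.append({"drug_id": f"{cls}_{flag}_{k:02d}",
                         "anchor_class": cls, "str_flag": flag})
    for k in range(1, spec.n_non_anchor + 1):
        rows.append({"drug_id": f"RX_{k:02d}", "anchor_class": "non_anchor",
                     "str_flag": "not_applicable"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fill-sequence simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PersonState:
    """Per-person parameters driving one fill sequence."""

    index_drug: str
    anchor_drugs: tuple[str, ...]
    supply_days: int
    stop_prob: float
    switch_prob: float
    p_ontime: float
    ontime_low: int
    ontime_high: int
    late_delay_mean: float
    death_day: int | None = None
    forced_stop_after_cycle: int | None = None
    forced_switch_after_cycle: int | None = None


def simulate_fill_sequence(state: PersonState, horizon_days: int,
                           rng: np.random.Generator
                           ) -> tuple[list[tuple[int, str, int]], list[dict]]:
    """Cycle-based refill simulation over 1-based days 1..horizon_days.

    Day 1 is always a fill of the index drug.  At each nominal exhaustion
    the person stops (permanently — no further anchor fills), possibly
    switches agent, and otherwise refills with the sampled delay.  Returns
    the fills as (day, drug_id, days_supply) plus a cycle-by-cycle event
    log for test introspection.
    """
    if horizon_days < 1:
        raise ValueError("horizon must be >= 1")
    fills: list[tuple[int, str, int]] = []
    events: list[dict] = []
    drug = state.index_drug
    day, due, cycle = 1, 1, 0
    if state.death_day is not None and state.death_day <= 1:
        return fills, [{"cycle": 0, "day": 1, "action": "death", "drug": drug}]
    while True:
        cycle += 1
        fills.append((day, drug, state.supply_days))
        events.append({"cycle": cycle, "day": day, "action": "fill", "drug": drug})
        due = max(day, due) + state.supply_days  # first day without supply
        forced_stop = state.forced_stop_after_cycle == cycle
        if forced_stop or (state.forced_stop_after_cycle is None
                           and rng.random() < state.stop_prob):
            events.append({"cycle": cycle, "day": due, "action": "stop", "drug": drug})
            break
        forced_switch = state.forced_switch_after_cycle == cycle
        if forced_switch or (state.forced_switch_after_cycle is None
                             and rng.random() < state.switch_prob):
            others = [d for d in state.anchor_drugs if d != drug]
            if others:
                drug = others[int(rng.integers(len(others)))]
                events.append({"cycle": cycle, "day": due, "action": "switch", "drug": drug})
        if rng.random() < state.p_ontime:
            delay = int(rng.integers(state.ontime_low, state.ontime_high + 1))
        else:
            delay = int(rng.geometric(min(1.0, 1.0 / state.late_delay_mean)))
        nxt = due + delay
        if nxt > horizon_days:
            events.append({"cycle": cycle, "day": nxt, "action": "end_of_followup",
                           "drug": drug})
            break
        if state.death_day is not None and nxt >= state.death_day:
            events.append({"cycle": cycle, "day": state.death_day, "action": "death",
                           "drug": drug})
            break
        day = nxt
    return fills, events


def _resolve_covariate(name: str, person: Mapping[str, object]) -> float:
    """Binary covariate value for a planted-effect key.

    Keys are either comorbidity flags (``cm_<name>``) or ``field:value``
    equality tests on beneficiary fields (e.g. ``sex:female``).
    """
    if name.startswith("cm_"):
        return float(person.get(name, 0))
    if ":" in name:
        field, value = name.split(":", 1)
        return float(str(person.get(field)) == value)
    raise ValueError(f"cannot resolve covariate-effect key {name!r}")


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def _sample_cat(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p /= p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def generate_bundle(params: SimulationParams,
                    config: AnalysisConfig | None = None) -> ClaimsBundle:
    """Generate a validated claims bundle plus ground-truth side table.

    Every beneficiary gets an anchor initiation inside the index window, a
    pre-index HIV diagnosis claim, and enrollment months spanning the pre
    and post periods; deaths, stays, switching, and refill noise follow the
    configured processes.  Identical parameters (including seed) give an
    identical bundle.
    """
    config = config or AnalysisConfig()
    catalog = build_drug_catalog(params.drug_catalog)
    cells: dict[str, list[str]] = {}
    for row in catalog.itertuples(index=False):
        if row.anchor_class != "non_anchor":
            cells.setdefault(f"{row.anchor_class}_{row.str_flag}", []).append(row.drug_id)
    anchor_ids = tuple(d for ds in cells.values() for d in ds)
    non_anchor_ids = list(catalog.loc[catalog["anchor_class"] == "non_anchor", "drug_id"])

    start = config.index_window_start
    window_days = (config.index_window_end - start).days + 1
    icd10_cutover = dt.date(2015, 10, 1)
    cm_names = list(params.demographics.comorbidity_prev)

    bene_rows, rx_rows, stay_rows, dx_rows, truth_rows = [], [], [], [], []
    for i in range(params.n_beneficiaries):
        rng = np.random.default_rng([params.seed, i])
        bid = f"B{i:06d}"
        index_date = start + dt.timedelta(days=int(rng.integers(window_days)))

        d = params.demographics
        band = _sample_cat(rng, d.age_band_probs)
        lo, hi = _AGE_BANDS[band]
        age_days = int(rng.uniform(lo * 365.25, (hi + 1) * 365.25))
        birth_date = index_date - dt.timedelta(days=age_days)
        person: dict[str, object] = {
            "beneficiary_id": bid,
            "birth_date": birth_date,
            "sex": _sample_cat(rng, d.sex_probs),
            "race_ethnicity": _sample_cat(rng, d.race_probs),
            "lis_status": _sample_cat(rng, d.lis_probs),
            "eligibility_reason": _sample_cat(rng, d.eligibility_probs),
            "census_region": _sample_cat(rng, d.region_probs),
            "metro": _sample_cat(rng, d.metro_probs),
            "plan_type": _sample_cat(rng, d.plan_probs),
        }
        for name in cm_names:
            person[f"cm_{name}"] = int(rng.random() < d.comorbidity_prev[name])
        # lognormal matched to the published mean/SD of the risk score
        sigma2 = math.log(1.0 + (d.hcc_sd / d.hcc_mean) ** 2)
        person["hcc_score"] = float(rng.lognormal(
            math.log(d.hcc_mean) - sigma2 / 2.0, math.sqrt(sigma2)))
        shape = (d.rx_per_month_mean / d.rx_per_month_sd) ** 2
        person["rx_per_month_pre"] = float(rng.gamma(shape, d.rx_per_month_mean / shape))
        person["county_code"] = (None if rng.random() < params.missing_county_prob
                                 else f"{int(rng.integers(1, 56)):02d}"
                                      f"{int(rng.integers(1, 400)):03d}")

        # planted effects on the stop hazard and refill delay
        h0 = params.discontinuation_hazard
        stop_logit = math.log(h0 / (1 - h0)) if 0 < h0 < 1 else (-math.inf if h0 == 0 else math.inf)
        delay_log = math.log(params.refill.mean_late_delay)
        for key, eff in params.covariate_effects.items():
            x = _resolve_covariate(key, person)
            stop_logit += eff.log_or_stop * x
            delay_log += eff.log_delay_mult * x
        stop_prob = 0.0 if stop_logit == -math.inf else (
            1.0 if stop_logit == math.inf else 1.0 / (1.0 + math.exp(-stop_logit)))
        delay_mean = max(1.0, math.exp(delay_log))

        death_day = None
        if rng.random() < params.annual_death_rate:
            death_day = int(rng.integers(2, config.followup_days + 1))
        person["death_date"] = (pd.Timestamp(index_date) + pd.Timedelta(days=death_day - 1)
                                if death_day is not None else pd.NaT)

        cell = _sample_cat(rng, params.anchor_choice_probs)
        index_drug = cells[cell][int(rng.integers(len(cells[cell])))]

        state = PersonState(
            index_drug=index_drug, anchor_drugs=anchor_ids,
            supply_days=params.supply_days, stop_prob=stop_prob,
            switch_prob=params.switch_prob, p_ontime=params.refill.p_ontime,
            ontime_low=params.refill.ontime_low, ontime_high=params.refill.ontime_high,
            late_delay_mean=delay_mean, death_day=death_day)
        fills, events = simulate_fill_sequence(state, config.followup_days, rng)
        for day, drug, supply in fills:
            rx_rows.append({"beneficiary_id": bid,
                            "fill_date": pd.Timestamp(index_date) + pd.Timedelta(days=day - 1),
                            "drug_id": drug, "days_supply": supply,
                            "quantity": float(supply)})

        # treatment-experienced: prior anchor filled from before the index
        # window through the pre-index period, switched at index
        experienced = rng.random() < params.prior_art_prob
        if experienced:
            others = [a for a in anchor_ids if a != index_drug]
            prior_drug = others[int(rng.integers(len(others)))]
            date = start - dt.timedelta(days=90)
            while date < index_date:
                rx_rows.append({"beneficiary_id": bid, "fill_date": pd.Timestamp(date),
                                "drug_id": prior_drug,
                                "days_supply": params.supply_days,
                                "quantity": float(params.supply_days)})
                date += dt.timedelta(days=params.supply_days)

        # chronic non-anchor background medication
        if non_anchor_ids and rng.random() < params.chronic_rx_prob:
            nd = non_anchor_ids[int(rng.integers(len(non_anchor_ids)))]
            horizon = death_day if death_day is not None else config.followup_days
            for off in range(-180, min(180, horizon - 1), 30):
                rx_rows.append({"beneficiary_id": bid,
                                "fill_date": pd.Timestamp(index_date) + pd.Timedelta(days=off),
                                "drug_id": nd, "days_supply": 30, "quantity": 30.0})

        # pre-index HIV diagnosis claims
        n_dx = 1 + int(rng.poisson(0.5))
        for _ in range(n_dx):
            days_before = int(rng.integers(1, config.pre_period_days + 1))
            service = index_date - dt.timedelta(days=days_before)
            system = "ICD9CM" if service < icd10_cutover else "ICD10CM"
            codes = config.hiv_codes[system]
            dx_rows.append({"beneficiary_id": bid, "service_date": pd.Timestamp(service),
                            "code": codes[int(rng.integers(len(codes)))],
                            "code_system": system,
                            "setting": "inpatient" if rng.random() < 0.2 else "outpatient"})

        # facility stays, independent of refill behaviour
        for _ in range(int(rng.poisson(params.stays.rate_per_year))):
            admit = int(rng.integers(1, config.followup_days + 1))
            if death_day is not None and admit >= death_day:
                continue
            dur = int(rng.geometric(1.0 / params.stays.mean_duration_days))
            discharge = min(admit + dur - 1, config.followup_days + 89)
            stay_rows.append({"beneficiary_id": bid,
                              "admit_date": pd.Timestamp(index_date) + pd.Timedelta(days=admit - 1),
                              "discharge_date": pd.Timestamp(index_date) + pd.Timedelta(days=discharge - 1),
                              "setting": _sample_cat(rng, params.stays.setting_probs)})

        months = months_touching(
            index_date - dt.timedelta(days=config.pre_period_days + 30),
            index_date + dt.timedelta(days=config.followup_days + 30))
        person["enrollment_months"] = format_months(months)
        person["birth_date"] = pd.Timestamp(birth_date)
        bene_rows.append(person)

        stop_ev = next((e for e in events if e["action"] == "stop"), None)
        switch_ev = next((e for e in events if e["action"] == "switch"), None)
        truth_rows.append({
            "beneficiary_id": bid, "index_date": pd.Timestamp(index_date),
            "index_drug_id": index_drug, "anchor_cell": cell,
            "treatment_experienced": experienced,
            "stop_prob": stop_prob, "delay_mean": delay_mean,
            "true_stop_day": stop_ev["day"] if stop_ev else None,
            "true_switch_day": switch_ev["day"] if switch_ev else None,
            "death_day": death_day, "n_fills": len(fills)})

    bene_cols = ["beneficiary_id", "birth_date", "sex", "race_ethnicity",
                 "lis_status", "eligibility_reason", "census_region", "metro",
                 "plan_type", "county_code", "hcc_score", "rx_per_month_pre",
                 "death_date", "enrollment_months"] + [f"cm_{n}" for n in cm_names]
    bundle = ClaimsBundle(
        beneficiaries=pd.DataFrame(bene_rows, columns=bene_cols),
        prescriptions=pd.DataFrame(rx_rows),
        stays=pd.DataFrame(stay_rows, columns=["beneficiary_id", "admit_date",
                                               "discharge_date", "setting"]),
        diagnoses=pd.DataFrame(dx_rows),
        drug_catalog=catalog,
        ground_truth=pd.DataFrame(truth_rows),
    ).sorted()
    violations = validate_bundle(bundle)
    if violations:  # pragma: no cover - generator bug guard
        raise AssertionError("generator produced an invalid bundle:\n" +
                             "\n".join(str(v) for v in violations[:10]))
    return bundle


# ---------------------------------------------------------------------------
# Edge-case scenario injection
# ---------------------------------------------------------------------------

SCENARIOS = ("death_in_followup", "eligibility_break", "dual_anchor_index",
             "fill_during_stay", "stay_mid_supply", "early_refill")


def inject_scenario(bundle: ClaimsBundle, scenario: str,
                    config: AnalysisConfig | None = None) -> ClaimsBundle:
    """Add a beneficiary exhibiting a named edge case.

    The returned bundle's ``markers`` table records the synthetic
    beneficiary id and condition so tests can assert on exactly the right
    person.  The injected person is otherwise cohort-eligible: index fill
    mid-window, pre-index HIV claim, full enrollment span.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    config = config or AnalysisConfig()
    out = bundle.copy()
    cat = out.drug_catalog
    anchors = sorted(cat.loc[cat["anchor_class"].isin(("PI", "NNRTI", "INSTI")), "drug_id"])
    if len(anchors) < 2:
        raise ValueError("bundle's drug catalog needs at least two anchor drugs")
    drug_a, drug_b = anchors[0], anchors[1]
    bid = f"SCN_{scenario}"
    index_date = dt.date(2015, 6, 1)

    def day(d: int) -> pd.Timestamp:
        return pd.Timestamp(index_date) + pd.Timedelta(days=d - 1)

    fills = [(d, drug_a, 30) for d in range(1, 362, 30)]  # perfect monthly refills
    stays: list[tuple[int, int]] = []
    death_date = pd.NaT
    months = set(months_touching(index_date - dt.timedelta(days=config.pre_period_days + 30),
                                 index_date + dt.timedelta(days=config.followup_days + 30)))
    if scenario == "death_in_followup":
        death_date = day(200)
        fills = [(d, drug_a, 30) for d in range(1, 182, 30)]
    elif scenario == "eligibility_break":
        months.discard((2015, 3))  # three months before index
    elif scenario == "dual_anchor_index":
        fills = [(1, drug_a, 30), (1, drug_b, 30)] + [(d, drug_a, 30)
                                                      for d in range(31, 362, 30)]
    elif scenario == "fill_during_stay":
        stays = [(30, 40)]
        fills = [(1, drug_a, 30), (33, drug_a, 30)] + [(d, drug_a, 30)
                                                       for d in range(71, 362, 30)]
    elif scenario == "stay_mid_supply":
        stays = [(11, 15)]
    elif scenario == "early_refill":
        # 30-day fill on day 1, same-drug refill on day 28 (carry-over case)
        fills = [(1, drug_a, 30), (28, drug_a, 30)] + [(d, drug_a, 30)
                                                       for d in range(61, 362, 30)]

    cm_cols = [c for c in out.beneficiaries.columns if c.startswith("cm_")]
    person = {"beneficiary_id": bid, "birth_date": pd.Timestamp(dt.date(1960, 1, 15)),
              "sex": "male", "race_ethnicity": "White", "lis_status": "full",
              "eligibility_reason": "disability", "census_region": "South",
              "metro": "urban", "plan_type": "other", "county_code": "01001",
              "hcc_score": 1.0, "rx_per_month_pre": 5.0, "death_date": death_date,
              "enrollment_months": format_months(months),
              **{c: 0 for c in cm_cols}}
    out.beneficiaries = pd.concat(
        [out.beneficiaries, pd.DataFrame([person])], ignore_index=True)
    out.prescriptions = pd.concat(
        [out.prescriptions, pd.DataFrame(
            [{"beneficiary_id": bid, "fill_date": day(d), "drug_id": g,
              "days_supply": s, "quantity": float(s)} for d, g, s in fills])],
        ignore_index=True)
    if stays:
        out.stays = pd.concat(
            [out.stays, pd.DataFrame(
                [{"beneficiary_id": bid, "admit_date": day(a),
                  "discharge_date": day(b), "setting": "hospital"}
                 for a, b in stays])], ignore_index=True)
    out.diagnoses = pd.concat(
        [out.diagnoses, pd.DataFrame(
            [{"beneficiary_id": bid, "service_date": day(-100), "code": "042",
              "code_system": "ICD9CM", "setting": "outpatient"}])],
        ignore_index=True)
    marker = pd.DataFrame([{"beneficiary_id": bid, "scenario": scenario}])
    out.markers = (marker if out.markers is None
                   else pd.concat([out.markers, marker], ignore_index=True))
    return out
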