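"""Claims tables, analysis configuration, validation, and file I/O.

The pipeline consumes five administrative-claims tables modelled on Medicare
research files: an enrollment/beneficiary summary, Part-D-like prescription
drug events, Part-A-like facility stays, diagnosis claims, and a drug catalog
mapping drug ids to antiretroviral "anchor" class (PI / NNRTI / INSTI) and
single- vs multi-tablet-regimen status.  Each table is held as a pandas
DataFrame with a documented column schema; :class:`ClaimsBundle` groups the
five together and :func:`validate_bundle` checks row-level invariants and
referential integrity.

Dates are stored as calendar dates throughout; conversion to 1-based
follow-up day indices happens only inside :mod:`artgaps.exposure`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# Enumerations (canonical spellings; normalization is case-insensitive)
# ---------------------------------------------------------------------------

SEX = ("male", "female")
RACE_ETHNICITY = ("White", "Black", "Hispanic", "Other")
LIS_STATUS = ("full", "partial", "none")
ELIGIBILITY_REASON = ("age", "disability", "esrd")
CENSUS_REGION = ("Northeast", "South", "Midwest", "West")
METRO = ("urban", "rural")
PLAN_TYPE = ("enhanced_alternative", "other")
STAY_SETTING = ("hospital", "snf", "hospice")
DX_SETTING = ("inpatient", "outpatient")
ANCHOR_CLASS = ("PI", "NNRTI", "INSTI", "non_anchor")
STR_FLAG = ("STR", "MTR", "not_applicable")
CODE_SYSTEM = ("ICD9CM", "ICD10CM")

#: HIV diagnosis code lists (decimal points removed).  ICD-9-CM: 042, V08,
#: 079.53.  ICD-10-CM: B20, B97.35, O98.711-713, O98.719, O98.72, O98.73, Z21.
DEFAULT_HIV_CODES: dict[str, list[str]] = {
    "ICD9CM": ["042", "V08", "07953"],
    "ICD10CM": [
        "B20", "B9735", "O98711", "O98712", "O98713",
        "O98719", "O9872", "O9873", "Z21",
    ],
}

#: Comorbidity groups summarised in the beneficiary table (``cm_`` columns).
DEFAULT_COMORBIDITIES = (
    "cardiovascular", "renal", "liver", "cancer", "mental_health",
    "substance_use", "lung", "autoimmune", "endocrine", "gi",
)


def normalize_code(code: str) -> str:
    """Canonical diagnosis-code form: uppercase, decimal point removed."""
    return str(code).replace(".", "").strip().upper()


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

class AnalysisConfig(BaseModel):
    """Tunable parameters of the adherence analysis.

    Defaults reproduce the study design this package implements: a 2014-2017
    index window, 365-day pre- and post-index periods, PDC thresholds
    0.70/0.80/0.90/0.95 with the optimal / intermediate / low categories cut
    at 0.95 and 0.70, eight longest-gap duration bins, and discontinuation
    defined as a fully observed continuous gap of >= 90 days.
    """

    index_window_start: dt.date = dt.date(2014, 1, 1)
    index_window_end: dt.date = dt.date(2017, 12, 31)
    followup_days: int = Field(365, gt=0)
    pre_period_days: int = Field(365, gt=0)
    discontinuation_gap_days: int = Field(90, gt=0)
    adherence_thresholds: list[float] = [0.70, 0.80, 0.90, 0.95]
    category_cutpoints: tuple[float, float] = (0.70, 0.95)
    gap_bins: list[int] = [7, 14, 30, 90, 120, 150, 180]
    hiv_codes: dict[str, list[str]] = DEFAULT_HIV_CODES
    facility_gap_policy: Literal["bridge", "split"] = "bridge"
    #: include post-index tail coverage from pre-index fills of non-index
    #: anchor drugs (off: that supply belongs to the pre-period regimen)
    include_preindex_anchor_tail: bool = False
    random_seed: int = 0

    @field_validator("adherence_thresholds")
    @classmethod
    def _thresholds_increasing(cls, v: list[float]) -> list[float]:
        if not v or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("adherence_thresholds must be strictly increasing")
        if any(not 0 < t <= 1 for t in v):
            raise ValueError("adherence_thresholds must lie in (0, 1]")
        return v

    @field_validator("gap_bins")
    @classmethod
    def _bins_increasing(cls, v: list[int]) -> list[int]:
        if not v or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("gap_bins must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "AnalysisConfig":
        if self.discontinuation_gap_days > self.followup_days:
            raise ValueError("discontinuation_gap_days must be <= followup_days")
        if self.category_cutpoints[0] >= self.category_cutpoints[1]:
            raise ValueError("category_cutpoints must be increasing")
        if self.index_window_end < self.index_window_start:
            raise ValueError("index window end precedes start")
        return self

    def hiv_code_set(self, code_system: str) -> frozenset[str]:
        return frozenset(normalize_code(c) for c in self.hiv_codes.get(code_system, []))

    def to_yaml(self, path: str | pathlib.Path | None = None) -> str:
        data = json.loads(self.model_dump_json())
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "AnalysisConfig":
        return cls.model_validate(yaml.safe_load(pathlib.Path(path).read_text()))


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

BENEFICIARY_COLUMNS = [
    "beneficiary_id", "birth_date", "sex", "race_ethnicity", "lis_status",
    "eligibility_reason", "census_region", "metro", "plan_type",
    "county_code", "hcc_score", "rx_per_month_pre", "death_date",
    "enrollment_months",
]
PRESCRIPTION_COLUMNS = ["beneficiary_id", "fill_date", "drug_id", "days_supply", "quantity"]
STAY_COLUMNS = ["beneficiary_id", "admit_date", "discharge_date", "setting"]
DIAGNOSIS_COLUMNS = ["beneficiary_id", "service_date", "code", "code_system", "setting"]
DRUG_CATALOG_COLUMNS = ["drug_id", "anchor_class", "str_flag"]

_DATE_COLUMNS = {
    "beneficiaries": ["birth_date", "death_date"],
    "prescriptions": ["fill_date"],
    "stays": ["admit_date", "discharge_date"],
    "diagnoses": ["service_date"],
    "drug_catalog": [],
}
_ENUM_COLUMNS: dict[tuple[str, str], tuple[str, ...]] = {
    ("beneficiaries", "sex"): SEX,
    ("beneficiaries", "race_ethnicity"): RACE_ETHNICITY,
    ("beneficiaries", "lis_status"): LIS_STATUS,
    ("beneficiaries", "eligibility_reason"): ELIGIBILITY_REASON,
    ("beneficiaries", "census_region"): CENSUS_REGION,
    ("beneficiaries", "metro"): METRO,
    ("beneficiaries", "plan_type"): PLAN_TYPE,
    ("stays", "setting"): STAY_SETTING,
    ("diagnoses", "code_system"): CODE_SYSTEM,
    ("diagnoses", "setting"): DX_SETTING,
    ("drug_catalog", "anchor_class"): ANCHOR_CLASS,
    ("drug_catalog", "str_flag"): STR_FLAG,
}
_SORT_KEYS = {
    "beneficiaries": ["beneficiary_id"],
    "prescriptions": ["beneficiary_id", "fill_date", "drug_id"],
    "stays": ["beneficiary_id", "admit_date", "discharge_date"],
    "diagnoses": ["beneficiary_id", "service_date", "code"],
    "drug_catalog": ["drug_id"],
}
TABLE_COLUMNS = {
    "beneficiaries": BENEFICIARY_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
    "stays": STAY_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "drug_catalog": DRUG_CATALOG_COLUMNS,
}


class BundleError(Exception):
    """Fatal problem reading, writing, or validating a claims bundle."""


@dataclasses.dataclass(frozen=True)
class Violation:
    """One data-quality finding: which table, which row, which rule."""

    table: str
    row: int | None
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"{self.table}[{self.row}]" if self.row is not None else self.table
        return f"{where}: {self.rule}: {self.message}"


@dataclasses.dataclass
class ClaimsBundle:
    """The five claims tables plus optional simulation side-tables.

    ``ground_truth`` (per-person planted parameters) and ``markers``
    (scenario annotations) are produced by :mod:`artgaps.synthetic_claims`
    for test introspection; they are not part of the claims schema proper.
    """

    beneficiaries: pd.DataFrame
    prescriptions: pd.DataFrame
    stays: pd.DataFrame
    diagnoses: pd.DataFrame
    drug_catalog: pd.DataFrame
    ground_truth: pd.DataFrame | None = None
    markers: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "beneficiaries": self.beneficiaries,
            "prescriptions": self.prescriptions,
            "stays": self.stays,
            "diagnoses": self.diagnoses,
            "drug_catalog": self.drug_catalog,
        }

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            **{k: v.copy() for k, v in self.tables().items()},
            ground_truth=None if self.ground_truth is None else self.ground_truth.copy(),
            markers=None if self.markers is None else self.markers.copy(),
        )

    def comorbidity_columns(self) -> list[str]:
        return [c for c in self.beneficiaries.columns if c.startswith("cm_")]

    def n_rows(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def sorted(self) -> "ClaimsBundle":
        """Deterministically ordered copy (beneficiary id, then dates)."""
        out = {}
        for name, df in self.tables().items():
            out[name] = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
        return ClaimsBundle(**out, ground_truth=self.ground_truth, markers=self.markers)


def empty_bundle(comorbidities: Iterable[str] = DEFAULT_COMORBIDITIES) -> ClaimsBundle:
    """A valid zero-row bundle with the full column schema."""
    bene_cols = BENEFICIARY_COLUMNS + [f"cm_{c}" for c in comorbidities]
    return ClaimsBundle(
        beneficiaries=pd.DataFrame(columns=bene_cols),
        prescriptions=pd.DataFrame(columns=PRESCRIPTION_COLUMNS),
        stays=pd.DataFrame(columns=STAY_COLUMNS),
        diagnoses=pd.DataFrame(columns=DIAGNOSIS_COLUMNS),
        drug_catalog=pd.DataFrame(columns=DRUG_CATALOG_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Enrollment-month helpers
# ---------------------------------------------------------------------------

def format_months(months: Iterable[tuple[int, int]]) -> str:
    """Encode a set of (year, month) pairs as ``YYYY-MM;YYYY-MM;...``."""
    return ";".join(f"{y:04d}-{m:02d}" for y, m in sorted(set(months)))


def parse_months(text: str) -> set[tuple[int, int]]:
    if not isinstance(text, str) or not text.strip():
        return set()
    out = set()
    for tok in text.split(";"):
        y, m = tok.strip().split("-")
        out.add((int(y), int(m)))
    return out


def months_touching(start: dt.date, end: dt.date) -> list[tuple[int, int]]:
    """Every calendar month with at least one day inside [start, end]."""
    if end < start:
        raise ValueError("end precedes start")
    months = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        months.append((y, m))
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return months


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: ClaimsBundle) -> list[Violation]:
    """Check all row-level invariants and referential constraints.

    Returns an empty list iff the bundle is valid.  Violations are data, not
    exceptions: callers that require validity should raise on a non-empty
    result (as :func:`read_bundle` does).
    """
    v: list[Violation] = []
    bene = bundle.beneficiaries
    rx = bundle.prescriptions
    stays = bundle.stays
    dx = bundle.diagnoses
    cat = bundle.drug_catalog

    for name, df in bundle.tables().items():
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            v.append(Violation(name, None, "schema", f"missing columns {missing}"))
    if v:
        return v

    # enum values
    for (table, col), allowed in _ENUM_COLUMNS.items():
        df = bundle.tables()[table]
        if len(df) == 0:
            continue
        bad = ~df[col].isin(allowed)
        for i in df.index[bad]:
            v.append(Violation(table, int(i), "enum",
                               f"{col}={df.at[i, col]!r} not in {allowed}"))

    # beneficiaries
    if len(bene):
        dup = bene["beneficiary_id"].duplicated()
        for i in bene.index[dup]:
            v.append(Violation("beneficiaries", int(i), "unique_id",
                               f"duplicate beneficiary_id {bene.at[i, 'beneficiary_id']}"))
        both = bene["death_date"].notna() & bene["birth_date"].notna()
        bad = both & (pd.to_datetime(bene["death_date"]) < pd.to_datetime(bene["birth_date"]))
        for i in bene.index[bad]:
            v.append(Violation("beneficiaries", int(i), "death_before_birth",
                               "death_date precedes birth_date"))
        for col, rule in (("hcc_score", "hcc_nonnegative"), ("rx_per_month_pre", "rx_nonnegative")):
            bad = pd.to_numeric(bene[col], errors="coerce") < 0
            for i in bene.index[bad.fillna(False)]:
                v.append(Violation("beneficiaries", int(i), rule, f"{col} < 0"))
        for i, text in bene["enrollment_months"].items():
            try:
                parse_months(text)
            except Exception:
                v.append(Violation("beneficiaries", int(i), "enrollment_months",
                                   f"unparseable enrollment_months {text!r}"))

    known_bene = set(bene["beneficiary_id"]) if len(bene) else set()
    known_drugs = set(cat["drug_id"]) if len(cat) else set()

    # prescriptions
    if len(rx):
        bad = pd.to_numeric(rx["days_supply"], errors="coerce").fillna(0) < 1
        for i in rx.index[bad]:
            v.append(Violation("prescriptions", int(i), "days_supply",
                               f"days_supply={rx.at[i, 'days_supply']!r} must be >= 1"))
        bad = pd.to_numeric(rx["quantity"], errors="coerce").fillna(0) <= 0
        for i in rx.index[bad]:
            v.append(Violation("prescriptions", int(i), "quantity", "quantity must be > 0"))
        for i in rx.index[~rx["beneficiary_id"].isin(known_bene)]:
            v.append(Violation("prescriptions", int(i), "unknown_beneficiary",
                               f"beneficiary_id {rx.at[i, 'beneficiary_id']!r} not in beneficiaries"))
        for i in rx.index[~rx["drug_id"].isin(known_drugs)]:
            v.append(Violation("prescriptions", int(i), "unknown_drug",
                               f"drug_id {rx.at[i, 'drug_id']!r} not in drug_catalog"))

    # stays
    if len(stays):
        bad = pd.to_datetime(stays["discharge_date"]) < pd.to_datetime(stays["admit_date"])
        for i in stays.index[bad]:
            v.append(Violation("stays", int(i), "stay_ordering",
                               "discharge_date precedes admit_date"))
        for i in stays.index[~stays["beneficiary_id"].isin(known_bene)]:
            v.append(Violation("stays", int(i), "unknown_beneficiary",
                               f"beneficiary_id {stays.at[i, 'beneficiary_id']!r} not in beneficiaries"))

    # diagnoses
    if len(dx):
        bad = dx["code"].astype(str).str.strip() == ""
        for i in dx.index[bad]:
            v.append(Violation("diagnoses", int(i), "empty_code", "code is empty"))
        for i in dx.index[~dx["beneficiary_id"].isin(known_bene)]:
            v.append(Violation("diagnoses", int(i), "unknown_beneficiary",
                               f"beneficiary_id {dx.at[i, 'beneficiary_id']!r} not in beneficiaries"))

    # drug catalog: STR/MTR applies exactly to anchor agents
    if len(cat):
        dup = cat["drug_id"].duplicated()
        for i in cat.index[dup]:
            v.append(Violation("drug_catalog", int(i), "unique_id",
                               f"duplicate drug_id {cat.at[i, 'drug_id']}"))
        is_anchor = cat["anchor_class"].isin(("PI", "NNRTI", "INSTI"))
        bad = (is_anchor & (cat["str_flag"] == "not_applicable")) | (
            ~is_anchor & (cat["str_flag"] != "not_applicable"))
        for i in cat.index[bad & cat["anchor_class"].isin(ANCHOR_CLASS)]:
            v.append(Violation("drug_catalog", int(i), "str_flag_consistency",
                               "str_flag must be not_applicable iff anchor_class is non_anchor"))
    return v


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _normalize_enums(name: str, df: pd.DataFrame) -> list[Violation]:
    """Case-insensitively map enum columns to canonical spellings in place."""
    problems: list[Violation] = []
    for (table, col), allowed in _ENUM_COLUMNS.items():
        if table != name or col not in df.columns or len(df) == 0:
            continue
        canon = {a.lower(): a for a in allowed}
        raw = df[col].astype(str).str.strip()
        mapped = raw.str.lower().map(canon)
        bad = mapped.isna() & df[col].notna()
        for i in df.index[bad]:
            problems.append(Violation(name, int(i), "enum",
                                      f"unknown {col} value {df.at[i, col]!r}"))
        df[col] = mapped.where(df[col].notna())
    return problems


def _parse_dates(name: str, df: pd.DataFrame) -> list[Violation]:
    problems: list[Violation] = []
    for col in _DATE_COLUMNS[name]:
        if col not in df.columns:
            continue
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        nullable = col == "death_date"
        blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
        bad = parsed.isna() & ~(blank if nullable else pd.Series(False, index=df.index))
        for i in df.index[bad]:
            problems.append(Violation(name, int(i), "date",
                                      f"unparseable {col} value {df.at[i, col]!r}"))
        df[col] = parsed
    return problems


def read_bundle(directory: str | pathlib.Path,
                config: AnalysisConfig | None = None,
                fmt: Literal["csv", "parquet"] = "csv") -> ClaimsBundle:
    """Read and validate a five-table bundle from ``directory``.

    Raises :class:`BundleError` naming the missing table, the offending row
    (unknown enum value, unparseable date), or the referential violations.
    """
    directory = pathlib.Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    problems: list[Violation] = []
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.{fmt}"
        if not path.exists():
            raise BundleError(f"missing table file for '{name}': {path}")
        if fmt == "csv":
            df = pd.read_csv(path, dtype={"beneficiary_id": str, "drug_id": str,
                                          "code": str, "county_code": str,
                                          "enrollment_months": str})
        else:
            df = pd.read_parquet(path)
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise BundleError(f"table '{name}' is missing columns {missing}")
        if fmt == "csv":
            problems += _parse_dates(name, df)
        problems += _normalize_enums(name, df)
        frames[name] = df
    if problems:
        raise BundleError("bundle failed to parse:\n" +
                          "\n".join(str(p) for p in problems[:50]))
    bundle = ClaimsBundle(**frames)
    violations = validate_bundle(bundle)
    if violations:
        raise BundleError("bundle failed validation:\n" +
                          "\n".join(str(v) for v in violations[:50]))
    return bundle


def write_bundle(bundle: ClaimsBundle, directory: str | pathlib.Path,
                 fmt: Literal["csv", "parquet"] = "csv") -> dict[str, dict]:
    """Write the five tables with deterministic row and column order.

    Returns (and writes as ``manifest.json``) a manifest of file names and
    row counts.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ordered = bundle.sorted()
    manifest: dict[str, dict] = {}
    for name, df in ordered.tables().items():
        cols = TABLE_COLUMNS[name] + [c for c in df.columns if c not in TABLE_COLUMNS[name]]
        df = df[cols]
        path = directory / f"{name}.{fmt}"
        if fmt == "csv":
            out = df.copy()
            for col in _DATE_COLUMNS[name]:
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
            out.to_csv(path, index=False)
        else:
            df.to_parquet(path, index=False)
        manifest[name] = {"file": path.name, "rows": int(len(df))}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
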