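"""Adherence, treatment-gap, and discontinuation outcomes.

From a :class:`~artgaps.exposure.DayCalendar` this module computes:

* PDC — proportion of days covered: covered days divided by eligible days
  (window length minus facility days), kept as an exact ratio and rounded
  only for presentation;
* threshold flags (PDC >= 0.70 / 0.80 / 0.90 / 0.95) and the three-level
  adherence category: optimal (PDC >= 0.95), intermediate (0.70 <= PDC <
  0.95), low (PDC < 0.70);
* continuous treatment-gap runs.  Under the default ``bridge`` policy a run
  is a maximal stretch of non-covered days containing at least one gap day;
  facility days inside the stretch contribute nothing to its length.  Under
  ``split`` a facility day terminates the run;
* discontinuation: a fully observed continuous gap of at least
  ``discontinuation_gap_days`` (default 90) gap days, with time to
  discontinuation = first gap day of the first qualifying run minus 1
  (days elapsed since the index date);
* cohort-level descriptive summaries, overall and by index anchor class.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig
from .exposure import COVERED, FACILITY, GAP, DayCalendar

CATEGORY_OPTIMAL = "optimal"
CATEGORY_INTERMEDIATE = "intermediate"
CATEGORY_LOW = "low"
CATEGORIES = (CATEGORY_OPTIMAL, CATEGORY_INTERMEDIATE, CATEGORY_LOW)


@dataclasses.dataclass(frozen=True)
class GapRun:
    """One continuous treatment gap.

    ``length`` counts gap days only; under the bridge policy facility days
    lying strictly inside the run separate its gap days without adding to
    the length, so length <= end_day - start_day + 1.
    """

    start_day: int
    end_day: int
    length: int


@dataclasses.dataclass
class AdherenceOutcome:
    beneficiary_id: str
    covered_days: int
    eligible_days: int
    facility_days: int
    pdc: Fraction | None
    threshold_flags: dict[float, bool]
    category: str | None
    gaps: list[GapRun]
    longest_gap: int
    longest_gap_bin: str
    n_gaps: int
    discontinued: bool
    time_to_discontinuation: int | None


def compute_pdc(calendar: DayCalendar) -> tuple[int, int, Fraction | None]:
    """Covered days, eligible days, and PDC as an exact fraction.

    Eligible days = window length minus facility days.  A person with zero
    eligible days (entire window in a facility) has undefined PDC and is
    excluded from adherence summaries.
    """
    covered = calendar.covered_days
    eligible = calendar.window_length - calendar.facility_days
    pdc = Fraction(covered, eligible) if eligible > 0 else None
    return covered, eligible, pdc


def classify_adherence(pdc: Fraction, config: AnalysisConfig) -> tuple[dict[float, bool], str]:
    """Threshold flags and 3-level category from the exact PDC ratio.

    Comparisons use exact rational arithmetic (thresholds interpreted as
    decimal literals), so a PDC of 347/365 ~ 0.9507 is optimal while
    346/365 ~ 0.9479 is not; rounding is never applied before comparison.
    """
    flags = {t: pdc >= Fraction(str(t)) for t in config.adherence_thresholds}
    low_cut, opt_cut = config.category_cutpoints
    if pdc >= Fraction(str(opt_cut)):
        cat = CATEGORY_OPTIMAL
    elif pdc >= Fraction(str(low_cut)):
        cat = CATEGORY_INTERMEDIATE
    else:
        cat = CATEGORY_LOW
    return flags, cat


def find_gap_runs(calendar: DayCalendar, policy: str = "bridge") -> list[GapRun]:
    """Continuous treatment gaps, sorted by start day.

    bridge: facility days inside a non-covered stretch bridge its gap days
    into one run (contributing 0 length); the run starts at the stretch's
    first gap day and ends at its last.  split: facility days terminate
    runs, so each run is a maximal stretch of pure gap days.
    """
    if policy not in ("bridge", "split"):
        raise ValueError(f"unknown gap policy {policy!r}")
    cls = calendar.day_class
    runs: list[GapRun] = []
    blocker = (cls == COVERED) if policy == "bridge" else (cls != GAP)
    n = len(cls)
    i = 0
    while i < n:
        if blocker[i]:
            i += 1
            continue
        j = i
        while j < n and not blocker[j]:
            j += 1
        seg = cls[i:j]
        gap_pos = np.flatnonzero(seg == GAP)
        if gap_pos.size:
            runs.append(GapRun(start_day=i + int(gap_pos[0]) + 1,
                               end_day=i + int(gap_pos[-1]) + 1,
                               length=int(gap_pos.size)))
        i = j
    return runs


def gap_bin_label(length: int, edges: Sequence[int]) -> str:
    """Duration-bin label for a longest gap of ``length`` days.

    With the default edges [7, 14, 30, 90, 120, 150, 180] the labels are
    "0 days (no gap)", "1 to 6 days", "7 to <14 days", ..., ">=180 days".
    """
    if length <= 0:
        return "0 days (no gap)"
    if length < edges[0]:
        return f"1 to {edges[0] - 1} days"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= length < hi:
            return f"{lo} to <{hi} days"
    return f">={edges[-1]} days"


def gap_bin_labels(edges: Sequence[int]) -> list[str]:
    """All bin labels in order, including the no-gap row."""
    labels = ["0 days (no gap)", f"1 to {edges[0] - 1} days"]
    labels += [f"{lo} to <{hi} days" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]} days")
    return labels


def summarize_gaps(runs: Sequence[GapRun], config: AnalysisConfig) -> tuple[int, str, int]:
    """(longest gap length, its duration bin, total number of gap runs)."""
    longest = max((r.length for r in runs), default=0)
    return longest, gap_bin_label(longest, config.gap_bins), len(runs)


def detect_discontinuation(runs: Sequence[GapRun],
                           config: AnalysisConfig) -> tuple[bool, int | None]:
    """First fully observed gap of >= discontinuation_gap_days gap days.

    Time to discontinuation is the number of days from the index date to
    the first day of that gap, i.e. start_day - 1 (a 30-day index supply
    never refilled gives a gap starting day 31 and a time of 30 days).
    """
    for run in runs:
        if run.length >= config.discontinuation_gap_days:
            return True, run.start_day - 1
    return False, None


def compute_outcome(calendar: DayCalendar, config: AnalysisConfig) -> AdherenceOutcome:
    """All outcome measures for one person."""
    covered, eligible, pdc = compute_pdc(calendar)
    if pdc is None:
        flags, cat = {t: False for t in config.adherence_thresholds}, None
    else:
        flags, cat = classify_adherence(pdc, config)
    runs = find_gap_runs(calendar, config.facility_gap_policy)
    longest, longest_bin, n_gaps = summarize_gaps(runs, config)
    discontinued, t_disc = detect_discontinuation(runs, config)
    return AdherenceOutcome(
        beneficiary_id=calendar.beneficiary_id,
        covered_days=covered,
        eligible_days=eligible,
        facility_days=calendar.facility_days,
        pdc=pdc,
        threshold_flags=flags,
        category=cat,
        gaps=runs,
        longest_gap=longest,
        longest_gap_bin=longest_bin,
        n_gaps=n_gaps,
        discontinued=discontinued,
        time_to_discontinuation=t_disc,
    )


def _threshold_col(t: float) -> str:
    return f"pdc_ge_{round(t * 100)}"


def outcomes_frame(calendars: Iterable[DayCalendar],
                   config: AnalysisConfig) -> pd.DataFrame:
    """One row of outcome measures per person."""
    rows = []
    for cal in calendars:
        o = compute_outcome(cal, config)
        row = {
            "beneficiary_id": o.beneficiary_id,
            "covered_days": o.covered_days,
            "eligible_days": o.eligible_days,
            "facility_days": o.facility_days,
            "pdc": float(o.pdc) if o.pdc is not None else np.nan,
            "category": o.category,
            "n_gaps": o.n_gaps,
            "longest_gap": o.longest_gap,
            "longest_gap_bin": o.longest_gap_bin,
            "any_gap_1d": o.n_gaps > 0,
            "any_gap_7d": any(r.length >= 7 for r in o.gaps),
            "discontinued": o.discontinued,
            "time_to_discontinuation": o.time_to_discontinuation,
        }
        for t, flag in o.threshold_flags.items():
            row[_threshold_col(t)] = flag
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("beneficiary_id", kind="mergesort").reset_index(drop=True)
    return df


def _stratum_summary(out: pd.DataFrame, config: AnalysisConfig) -> dict[str, float]:
    n = len(out)
    s: dict[str, float] = {"N": n}
    defined = out[out["pdc"].notna()] if n else out
    s["PDC mean"] = float(defined["pdc"].mean()) if len(defined) else np.nan
    s["PDC sd"] = float(defined["pdc"].std(ddof=1)) if len(defined) > 1 else np.nan
    for t in config.adherence_thresholds:
        col = _threshold_col(t)
        s[f"PDC >= {t:.2f} n"] = int(defined[col].sum()) if len(defined) else 0
        s[f"PDC >= {t:.2f} %"] = 100.0 * defined[col].mean() if len(defined) else np.nan
    for cat, label in ((CATEGORY_LOW, "PDC < 0.70"),
                       (CATEGORY_INTERMEDIATE, "PDC 0.70 to < 0.95"),
                       (CATEGORY_OPTIMAL, "PDC >= 0.95")):
        k = int((defined["category"] == cat).sum()) if len(defined) else 0
        s[f"{label} n"] = k
        s[f"{label} %"] = 100.0 * k / len(defined) if len(defined) else np.nan
    for label in gap_bin_labels(config.gap_bins):
        k = int((out["longest_gap_bin"] == label).sum()) if n else 0
        s[f"Longest gap {label} n"] = k
        s[f"Longest gap {label} %"] = 100.0 * k / n if n else np.nan
    for col, label in (("any_gap_1d", ">=1 day"), ("any_gap_7d", ">=7 days")):
        k = int(out[col].sum()) if n else 0
        s[f"Any gap {label} n"] = k
        s[f"Any gap {label} %"] = 100.0 * k / n if n else np.nan
    s["Gaps per person mean"] = float(out["n_gaps"].mean()) if n else np.nan
    k = int(out["discontinued"].sum()) if n else 0
    s["Discontinuation n"] = k
    s["Discontinuation %"] = 100.0 * k / n if n else np.nan
    t = out.loc[out["discontinued"], "time_to_discontinuation"].astype(float) if n else pd.Series(dtype=float)
    s["Time to discontinuation mean"] = float(t.mean()) if len(t) else np.nan
    s["Time to discontinuation sd"] = float(t.std(ddof=1)) if len(t) > 1 else np.nan
    s["Time to discontinuation median"] = float(t.median()) if len(t) else np.nan
    s["Time to discontinuation q1"] = float(t.quantile(0.25)) if len(t) else np.nan
    s["Time to discontinuation q3"] = float(t.quantile(0.75)) if len(t) else np.nan
    return s


def summarize_cohort(outcomes: pd.DataFrame, cohort: pd.DataFrame,
                     config: AnalysisConfig) -> pd.DataFrame:
    """Descriptive outcome summary, overall and by index anchor class.

    Rows are measures (N; PDC mean/SD; threshold counts; category counts;
    longest-gap duration bins including the "0 days (no gap)" row; any-gap
    at the >=1-day and >=7-day definitions; discontinuation;
    time-to-discontinuation distribution among discontinuers).  Columns are
    the Overall stratum followed by one column per anchor class, plus one
    per anchor class x STR stratum.
    """
    merged = outcomes.merge(
        cohort[["beneficiary_id", "anchor_class", "str_flag"]],
        on="beneficiary_id", how="left", validate="one_to_one")
    strata: dict[str, pd.DataFrame] = {"Overall": merged}
    for cls in ("INSTI", "NNRTI", "PI"):
        strata[cls] = merged[merged["anchor_class"] == cls]
    for (cls, flag), grp in merged.groupby(["anchor_class", "str_flag"]):
        if cls == "PI":
            continue  # no PI single-tablet products in the study window
        strata[f"{cls} {flag}"] = grp
    table = {name: _stratum_summary(df, config) for name, df in strata.items()}
    return pd.DataFrame(table)
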