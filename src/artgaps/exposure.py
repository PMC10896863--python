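"""Day-level drug-coverage construction for the follow-up window.

Converts a person's anchor-medication fills and facility stays into a
classification of each follow-up day (1-based; the index fill date is day 1)
as ``covered``, ``facility``, or ``gap``:

* a fill on day *d* with *s* days' supply covers days *d .. d+s-1* when
  nothing intervenes;
* same-drug carry-over: if a drug is refilled before its previous supply is
  exhausted, the new supply starts the day after the previous supply ends
  (a 30-day fill on day 1 refilled on day 28 has its second start adjusted
  to day 31);
* facility stays (hospital / skilled nursing facility / hospice) are
  excluded from both numerator and denominator: a stay day is classed
  ``facility`` regardless of supply, and supply is conserved — consumption
  skips stay days and resumes afterwards (stockpiling).  A fill whose
  adjusted start lands inside a stay therefore starts the day after the
  merged stay ends;
* coverage is the union over all anchor drugs ("any anchor" adherence);
  there is no carry-over across distinct drugs.

The engine works on merged day intervals rather than a day-by-day loop; the
test suite checks it exactly against a naive per-day simulation oracle.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, ClaimsBundle

COVERED, FACILITY, GAP = 0, 1, 2
_CLASS_CHAR = np.array(["C", "F", "G"])


def to_day_index(date: dt.date | pd.Timestamp, index_date: dt.date | pd.Timestamp) -> int:
    """1-based follow-up day index: the index date maps to day 1."""
    return (pd.Timestamp(date) - pd.Timestamp(index_date)).days + 1


def merge_day_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of inclusive day intervals, merging overlaps and adjacency.

    Adjacent stays (e.g. days 10-12 and 13-14) form one contiguous blocked
    stretch of days, so they merge.  Idempotent.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e >= s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def facility_intervals(stays: pd.DataFrame | Sequence[tuple[int, int]],
                       index_date: dt.date | None = None,
                       window_length: int = 365) -> list[tuple[int, int]]:
    """Merged facility-day intervals clipped to [1, window_length].

    ``stays`` is either a FacilityStay frame (with ``index_date`` given) or an
    iterable of (admit_day, discharge_day) pairs already in day space.
    """
    if isinstance(stays, pd.DataFrame):
        if index_date is None:
            raise ValueError("index_date required with a stays frame")
        pairs = [(to_day_index(a, index_date), to_day_index(d, index_date))
                 for a, d in zip(stays["admit_date"], stays["discharge_date"])]
    else:
        pairs = [(int(a), int(d)) for a, d in stays]
    clipped = [(max(1, s), min(window_length, e)) for s, e in pairs]
    return merge_day_intervals([(s, e) for s, e in clipped if s <= e])


def facility_day_set(stays, index_date=None, window_length: int = 365) -> set[int]:
    out: set[int] = set()
    for s, e in facility_intervals(stays, index_date, window_length):
        out.update(range(s, e + 1))
    return out


@dataclasses.dataclass
class AdjustedFill:
    """One fill after carry-over and facility-stay adjustment."""

    drug_id: str
    fill_day: int
    adjusted_start: int
    days_supply: int
    supplied_intervals: list[tuple[int, int]]
    days_in_window: int


def _allocate(start: int, supply: int,
              fac: Sequence[tuple[int, int]]) -> tuple[list[tuple[int, int]], int]:
    """Consume ``supply`` days on non-facility days >= ``start``.

    Returns the supplied intervals and the pointer (day after the last
    supplied day).  Facility intervals are merged and sorted; days beyond
    them are free.
    """
    covered: list[tuple[int, int]] = []
    day = start
    k = supply
    for fs, fe in fac:
        if k == 0:
            break
        if fe < day:
            continue
        if fs > day:
            take = min(k, fs - day)
            covered.append((day, day + take - 1))
            k -= take
            day += take
            if k == 0:
                break
        if day >= fs:
            day = fe + 1
    if k:
        covered.append((day, day + k - 1))
        day += k
    return covered, day


def adjust_fill_schedule(fills: Iterable[tuple[int, str, int]],
                         fac: Sequence[tuple[int, int]] = (),
                         window_length: int = 365) -> list[AdjustedFill]:
    """Apply carry-over and stockpiling adjustments to a fill sequence.

    ``fills`` are (fill_day, drug_id, days_supply) triples for one person;
    multiple same-drug fills on one day have their supplies summed.  For
    each drug a pointer tracks the day after its last supplied day; a fill's
    adjusted start is max(fill day, pointer), pushed past facility days.
    Supply consumption is truncated at the window end for measurement but
    the pointer advances logically beyond it.
    """
    combined: dict[tuple[int, str], int] = {}
    for day, drug, supply in fills:
        if supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {supply}")
        key = (int(day), str(drug))
        combined[key] = combined.get(key, 0) + int(supply)
    fac = merge_day_intervals(fac)
    pointers: dict[str, int] = {}
    out: list[AdjustedFill] = []
    for (day, drug), supply in sorted(combined.items()):
        start = max(day, pointers.get(drug, day))
        supplied, nxt = _allocate(start, supply, fac)
        pointers[drug] = nxt
        in_window = sum(min(e, window_length) - s + 1
                        for s, e in supplied if s <= window_length)
        out.append(AdjustedFill(drug, day, supplied[0][0], supply, supplied, in_window))
    return out


@dataclasses.dataclass
class DayCalendar:
    """Per-person classification of follow-up days 1..window_length."""

    beneficiary_id: str
    window_length: int
    day_class: np.ndarray  # int8, values COVERED / FACILITY / GAP
    adjusted_fills: list[AdjustedFill]

    @property
    def covered_days(self) -> int:
        return int(np.sum(self.day_class == COVERED))

    @property
    def facility_days(self) -> int:
        return int(np.sum(self.day_class == FACILITY))

    @property
    def gap_days(self) -> int:
        return int(np.sum(self.day_class == GAP))

    def to_string(self) -> str:
        """One character per day: C (covered) / F (facility) / G (gap)."""
        return "".join(_CLASS_CHAR[self.day_class])

    @classmethod
    def from_string(cls, s: str, beneficiary_id: str = "") -> "DayCalendar":
        codes = {"C": COVERED, "F": FACILITY, "G": GAP}
        arr = np.array([codes[c] for c in s], dtype=np.int8)
        return cls(beneficiary_id, len(arr), arr, [])


def day_calendar_from_days(fills: Iterable[tuple[int, str, int]],
                           stay_intervals: Sequence[tuple[int, int]] = (),
                           window_length: int = 365,
                           beneficiary_id: str = "") -> DayCalendar:
    """Build a calendar from day-space fills and stay intervals.

    Fills with start day beyond the window contribute nothing; fills with
    nonpositive day indices (pre-index tail supply) are allowed and have
    their in-window portion counted.
    """
    fac = facility_intervals(list(stay_intervals), window_length=window_length)
    day_class = np.full(window_length, GAP, dtype=np.int8)
    for s, e in fac:
        day_class[s - 1:e] = FACILITY
    adjusted = adjust_fill_schedule(
        [(d, g, s) for d, g, s in fills if d <= window_length],
        fac, window_length)
    for af in adjusted:
        for s, e in af.supplied_intervals:
            s, e = max(1, s), min(window_length, e)
            if s <= e:
                day_class[s - 1:e] = COVERED
    return DayCalendar(beneficiary_id, window_length, day_class, adjusted)


def build_day_calendar(fills: pd.DataFrame, stays: pd.DataFrame,
                       index_date: dt.date | pd.Timestamp,
                       config: AnalysisConfig,
                       beneficiary_id: str = "") -> DayCalendar:
    """Build a calendar from one person's anchor fills and stays (date space).

    ``fills`` must already be restricted to anchor-class drugs; fills dated
    inside the follow-up window are used, and (when
    ``config.include_preindex_anchor_tail`` is set) pre-index fills are kept
    so their tail supply can reach into the window.
    """
    w = config.followup_days
    day_fills = []
    for date, drug, supply in zip(fills["fill_date"], fills["drug_id"], fills["days_supply"]):
        d = to_day_index(date, index_date)
        if 1 <= d <= w or (config.include_preindex_anchor_tail and d < 1):
            day_fills.append((d, drug, int(supply)))
    stay_pairs = [(to_day_index(a, index_date), to_day_index(d, index_date))
                  for a, d in zip(stays["admit_date"], stays["discharge_date"])]
    return day_calendar_from_days(day_fills, stay_pairs, w, beneficiary_id)


def calendars_for_cohort(bundle: ClaimsBundle, cohort: pd.DataFrame,
                         config: AnalysisConfig) -> dict[str, DayCalendar]:
    """Day calendars for every cohort member, keyed by beneficiary id.

    Coverage is taken over *any* anchor drug; by default pre-index fills
    (including pre-index fills of non-index anchors) contribute nothing.
    """
    anchor_ids = set(
        bundle.drug_catalog.loc[
            bundle.drug_catalog["anchor_class"].isin(("PI", "NNRTI", "INSTI")), "drug_id"])
    rx = bundle.prescriptions
    rx = rx[rx["drug_id"].isin(anchor_ids)]
    rx_by_bene = {k: g for k, g in rx.groupby("beneficiary_id")}
    stays_by_bene = {k: g for k, g in bundle.stays.groupby("beneficiary_id")}
    empty_rx = rx.iloc[0:0]
    empty_stays = bundle.stays.iloc[0:0]
    out: dict[str, DayCalendar] = {}
    for row in cohort.itertuples(index=False):
        bid = row.beneficiary_id
        out[bid] = build_day_calendar(
            rx_by_bene.get(bid, empty_rx), stays_by_bene.get(bid, empty_stays),
            row.index_date, config, beneficiary_id=bid)
    return out
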