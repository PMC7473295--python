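"""Case ascertainment from coded clinical records.

Each person is tagged as a clinical case (or not) for a condition when at
least one qualifying record — a GP event whose Read code is on the
event/medication list, or a hospital episode carrying a listed ICD-10
diagnosis — falls inside the condition's ascertainment window:

* ``EVER`` — any record from the source's data start up to the interview
  date (hospital lookback reaches further back than GP lookback).
* ``CURRENT_12M`` — a record dated within the closed interval
  [interview_date − 12 months, interview_date]; the 12-month subtraction is
  a calendar-month shift with day-of-month clamped at month end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from fractions import Fraction

import numpy as np
import pandas as pd

from .codelists import ConditionCodeSet, Window, normalize_icd10, normalize_read
from .linkage import PlatformRecordSet
from ._rounding import round_half_up

__all__ = [
    "CASE_TAG_COLUMNS",
    "SourceAttribution",
    "ascertain",
    "attribute_sources",
    "coverage_undercount",
]

logger = logging.getLogger(__name__)

CASE_TAG_COLUMNS = ["alf", "condition_id", "is_case", "via_gp", "via_hospital", "first_event_date"]

DEFAULT_GP_START = date(2010, 1, 1)
DEFAULT_HOSPITAL_START = date(2002, 1, 1)


@dataclass(frozen=True)
class SourceAttribution:
    """Partition of clinical cases by identifying source."""

    condition_id: str
    gp_only: int
    hospital_only: int
    both: int

    @property
    def total(self) -> int:
        return self.gp_only + self.hospital_only + self.both

    @property
    def percentages(self) -> tuple[int, int, int]:
        """Whole-number shares of the total; (0, 0, 0) for an empty partition."""
        if self.total == 0:
            return (0, 0, 0)
        return tuple(
            int(round_half_up(100 * count / self.total, 0))
            for count in (self.gp_only, self.hospital_only, self.both)
        )


def _qualifying_gp(
    platform: PlatformRecordSet,
    code_set: ConditionCodeSet,
    window: Window,
    gp_data_start: date,
    min_gp_events: int,
) -> pd.DataFrame:
    """Per-alf first qualifying GP event date (alfs meeting min_gp_events)."""
    events = platform.gp_events
    if events.empty or not code_set.gp_codes:
        return pd.DataFrame(columns=["alf", "first_gp"])
    wanted = {c.normalized for c in code_set.gp_codes}
    codes = events["read_code"].astype(str)
    bad = codes.str.strip() == ""
    if bad.any():
        logger.warning("ascertain(%s): %d malformed GP codes ignored", code_set.condition_id, int(bad.sum()))
    normalized = codes.str.strip().str.rstrip(".")
    hit = events.loc[normalized.isin(wanted) & ~bad, ["alf", "event_date"]]
    if hit.empty:
        return pd.DataFrame(columns=["alf", "first_gp"])
    merged = hit.merge(platform.persons[["alf", "interview_date"]], on="alf", how="left")
    lower = _window_lower(merged["interview_date"], window, gp_data_start)
    in_window = (merged["event_date"] >= lower) & (merged["event_date"] <= merged["interview_date"])
    merged = merged.loc[in_window]
    grouped = merged.groupby("alf")["event_date"]
    summary = grouped.agg(first_gp="min", n="size").reset_index()
    summary = summary.loc[summary["n"] >= min_gp_events, ["alf", "first_gp"]]
    return summary


def _qualifying_hospital(
    platform: PlatformRecordSet,
    code_set: ConditionCodeSet,
    window: Window,
    hospital_data_start: date,
    icd_prefix_matching: bool,
) -> pd.DataFrame:
    episodes = platform.hospital_episodes
    if episodes.empty or not code_set.diagnosis_codes:
        return pd.DataFrame(columns=["alf", "first_hosp"])
    # all diagnosis positions (primary and secondary) are eligible
    exploded = episodes.assign(code=episodes["icd10_codes"].astype(str).str.split(";")).explode("code")
    codes = exploded["code"].astype(str).str.strip()
    bad = codes == ""
    if bad.any():
        logger.warning(
            "ascertain(%s): %d malformed hospital codes ignored", code_set.condition_id, int(bad.sum())
        )
    normalized = codes.str.upper().str.replace(".", "", regex=False)
    entries = sorted(c.normalized for c in code_set.diagnosis_codes)
    if icd_prefix_matching:
        mask = np.zeros(len(normalized), dtype=bool)
        for entry in entries:
            mask |= normalized.str.startswith(entry).values
    else:
        mask = normalized.isin(entries).values
    hit = exploded.loc[mask & ~bad.values, ["alf", "admission_date"]]
    if hit.empty:
        return pd.DataFrame(columns=["alf", "first_hosp"])
    merged = hit.merge(platform.persons[["alf", "interview_date"]], on="alf", how="left")
    lower = _window_lower(merged["interview_date"], window, hospital_data_start)
    in_window = (merged["admission_date"] >= lower) & (
        merged["admission_date"] <= merged["interview_date"]
    )
    merged = merged.loc[in_window]
    return merged.groupby("alf")["admission_date"].min().rename("first_hosp").reset_index()


def _window_lower(interview: pd.Series, window: Window, source_start: date) -> pd.Series:
    if window is Window.CURRENT_12M:
        lower = interview - pd.DateOffset(months=12)
        return lower.clip(lower=pd.Timestamp(source_start))
    return pd.Series(pd.Timestamp(source_start), index=interview.index)


def ascertain(
    platform: PlatformRecordSet,
    code_set: ConditionCodeSet,
    icd_prefix_matching: bool = True,
    *,
    min_gp_events: int = 1,
    gp_data_start: date = DEFAULT_GP_START,
    hospital_data_start: date = DEFAULT_HOSPITAL_START,
) -> pd.DataFrame:
    """Tag every platform person for one condition.

    Returns one row per person with columns ``alf, condition_id, is_case,
    via_gp, via_hospital, first_event_date`` (``first_event_date`` is NaT for
    non-cases).  A single qualifying record suffices by default;
    ``min_gp_events`` raises the GP threshold for the stricter
    two-visits-or-one-hospitalisation definition.
    """
    if not code_set.all_codes():
        raise ValueError(f"code set for {code_set.condition_id} is empty")
    window = code_set.window
    gp = _qualifying_gp(platform, code_set, window, gp_data_start, min_gp_events)
    hosp = _qualifying_hospital(platform, code_set, window, hospital_data_start, icd_prefix_matching)

    tags = platform.persons[["alf"]].copy()
    tags["condition_id"] = code_set.condition_id
    tags = tags.merge(gp, on="alf", how="left").merge(hosp, on="alf", how="left")
    tags["first_gp"] = pd.to_datetime(tags["first_gp"])
    tags["first_hosp"] = pd.to_datetime(tags["first_hosp"])
    tags["via_gp"] = tags["first_gp"].notna()
    tags["via_hospital"] = tags["first_hosp"].notna()
    tags["is_case"] = tags["via_gp"] | tags["via_hospital"]
    tags["first_event_date"] = tags[["first_gp", "first_hosp"]].min(axis=1)
    return tags[CASE_TAG_COLUMNS]


def attribute_sources(tags: pd.DataFrame, condition_id: str) -> SourceAttribution:
    """Partition a condition's cases into GP-only / hospital-only / both."""
    sub = tags.loc[(tags["condition_id"] == condition_id) & tags["is_case"]]
    gp_only = int((sub["via_gp"] & ~sub["via_hospital"]).sum())
    hospital_only = int((~sub["via_gp"] & sub["via_hospital"]).sum())
    both = int((sub["via_gp"] & sub["via_hospital"]).sum())
    return SourceAttribution(condition_id, gp_only, hospital_only, both)


def coverage_undercount(gp_only_count: int, coverage: float) -> int:
    """Estimated additional GP-only cases had all practices contributed.

    With a fraction ``coverage`` of practices supplying data, the observed
    GP-only count scales up by ``1/coverage``; the undercount is
    ``floor(gp_only_count * (1/coverage - 1))``.  Computed in exact rational
    arithmetic so that e.g. (32, 0.8) yields 8, not 7.999… truncated.
    """
    if gp_only_count < 0:
        raise ValueError("gp_only_count must be >= 0")
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    frac = Fraction(coverage).limit_denominator(10**6)
    return int(math.floor(gp_only_count * (1 / frac - 1)))
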