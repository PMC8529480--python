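"""Frequent-user and frail-elderly cohort identification and annual summaries.

A *frequent user* is a patient with at least ``frequent_threshold`` ambulance
rides to regional care providers within one calendar year (default 4, the
threshold commonly used in the frequent-user literature). *Frail elderly*
users are the frequent users aged ``frail_age_min`` or more (default 70).
Among their planned (B) rides, those for dialysis, radiation therapy or
hyperbaric medicine — the predictable, recurring "known" needs — are tagged
B-DRH; all other planned rides are B-other. A patient can appear in both
groups in the same year because of comorbidity.

Percentages follow a single rounding rule throughout: half away from zero to
the nearest integer (so 82.53% prints as 83 and 51.61% as 52).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .event_log import PatientTrace, RideRecord

__all__ = [
    "CohortParams",
    "AnnualSummary",
    "round_half_up",
    "share_pct",
    "percent_change",
    "classify_drh",
    "yearly_memberships",
    "summarize_annual",
    "summarize_needs_urgency",
]

DEFAULT_DRH_KEYWORDS = frozenset({"dialysis", "radiation", "hyperbaric"})

MEMBERSHIP_COLUMNS = [
    "year",
    "patient_id",
    "calls_in_year",
    "calls_A",
    "calls_B",
    "calls_B_drh",
    "calls_B_other",
    "age",
    "is_frequent",
    "is_frail_elderly",
    "has_A_ride",
    "has_B_ride",
    "is_B_DRH",
    "is_B_other",
]


@dataclass(frozen=True)
class CohortParams:
    """Tunable cohort definitions.

    ``frail_age_mode`` selects how a patient's age for a year is evaluated:
    ``"first_ride"`` (default) uses the recorded age at their first ride of
    the year; ``"max_ride"`` uses the maximum recorded age over the year.
    ``year_range`` restricts the analysis to an inclusive span of calendar
    years; ``None`` means every year present in the data.
    """

    frequent_threshold: int = 4
    frail_age_min: int = 70
    drh_keywords: frozenset[str] = DEFAULT_DRH_KEYWORDS
    year_range: tuple[int, int] | None = None
    frail_age_mode: str = "first_ride"

    def __post_init__(self) -> None:
        if self.frequent_threshold < 1:
            raise ValueError("frequent_threshold must be >= 1")
        if self.frail_age_min < 0:
            raise ValueError("frail_age_min must be >= 0")
        if self.year_range is not None and self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be non-empty")
        if self.frail_age_mode not in ("first_ride", "max_ride"):
            raise ValueError("frail_age_mode must be 'first_ride' or 'max_ride'")
        object.__setattr__(self, "drh_keywords", frozenset(
            k.lower() for k in self.drh_keywords
        ))

    def years(self, present: Iterable[int]) -> list[int]:
        if self.year_range is not None:
            return list(range(self.year_range[0], self.year_range[1] + 1))
        return sorted(set(present))


def round_half_up(value: float | Decimal) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def share_pct(part: int, whole: int) -> int:
    """``part`` as an integer percentage of ``whole`` (half away from zero)."""
    if whole <= 0:
        raise ValueError("share_pct requires whole > 0")
    if part > whole:
        raise ValueError("share_pct requires part <= whole")
    return round_half_up(Decimal(100 * part) / Decimal(whole))


def percent_change(earlier: int, later: int) -> int:
    """Signed integer percent change from ``earlier`` to ``later``."""
    if earlier <= 0:
        raise ValueError("percent_change requires earlier > 0")
    return round_half_up(Decimal(100 * (later - earlier)) / Decimal(earlier))


def classify_drh(record: RideRecord, params: CohortParams | None = None) -> bool:
    """True iff the ride is planned (B) transport for a DRH need.

    The DRH need is detected by case-insensitive substring search of the
    keyword set in both the destination and the specialty label, because
    source systems encode it in either (e.g. a destination label
    ``"RegHospital 1-dialysis"``).
    """
    params = params or CohortParams()
    if record.urgency != "B":
        return False
    haystack = f"{record.destination} {record.specialty}".lower()
    return any(keyword in haystack for keyword in params.drh_keywords)


def _year_age(events: Sequence[RideRecord], mode: str) -> int | None:
    ages = [e.age for e in events if e.age is not None]
    if mode == "first_ride":
        for e in events:
            if e.age is not None:
                return e.age
        return None
    return max(ages) if ages else None


def yearly_memberships(
    traces: Iterable[PatientTrace], params: CohortParams | None = None
) -> pd.DataFrame:
    """Per-(patient, year) call counts and cohort flags.

    Returns one row per patient per calendar year with at least one ride,
    with columns :data:`MEMBERSHIP_COLUMNS`. All rides count toward
    ``calls_in_year``, including rides to an ``"Unknown"`` destination —
    the frequency criterion is a ride count, not a provider count.
    """
    params = params or CohortParams()
    rows = []
    for trace in traces:
        by_year: dict[int, list[RideRecord]] = {}
        for event in trace.events:
            by_year.setdefault(event.year, []).append(event)
        for year, events in sorted(by_year.items()):
            if params.year_range is not None and not (
                params.year_range[0] <= year <= params.year_range[1]
            ):
                continue
            calls = len(events)
            calls_a = sum(1 for e in events if e.urgency_class == "A")
            calls_b_drh = sum(1 for e in events if classify_drh(e, params))
            calls_b = calls - calls_a
            age = _year_age(events, params.frail_age_mode)
            is_frequent = calls >= params.frequent_threshold
            rows.append(
                {
                    "year": year,
                    "patient_id": trace.patient_id,
                    "calls_in_year": calls,
                    "calls_A": calls_a,
                    "calls_B": calls_b,
                    "calls_B_drh": calls_b_drh,
                    "calls_B_other": calls_b - calls_b_drh,
                    "age": age,
                    "is_frequent": is_frequent,
                    "is_frail_elderly": bool(
                        is_frequent and age is not None and age >= params.frail_age_min
                    ),
                    "has_A_ride": calls_a > 0,
                    "has_B_ride": calls_b > 0,
                    "is_B_DRH": calls_b_drh > 0,
                    "is_B_other": (calls_b - calls_b_drh) > 0,
                }
            )
    frame = pd.DataFrame(rows, columns=MEMBERSHIP_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["year", "patient_id"], ignore_index=True)
        frame["age"] = frame["age"].astype("Int64")
    return frame


@dataclass
class AnnualSummary:
    """Per-year rows plus a totals row with distinct-patient counts."""

    per_year: pd.DataFrame
    totals: pd.Series


def _pct_or_na(part: int, whole: int):
    return share_pct(part, whole) if whole > 0 else pd.NA


def summarize_annual(
    memberships: pd.DataFrame, params: CohortParams | None = None
) -> AnnualSummary:
    """Annual utilization overview: all patients, frequent users, frail elderly.

    Per year: patient and call counts for the full population, the
    frequent-user subset, and the frail-elderly subset of frequent users;
    frequent calls as a percentage of all calls; frail calls as a percentage
    of frequent calls. The totals row sums the annual columns and separately
    counts distinct patients over the whole period (a patient frequent in
    three years is three annual counts but one distinct patient).
    """
    params = params or CohortParams()
    years = params.years(memberships["year"].unique() if len(memberships) else [])
    rows = []
    for year in years:
        sub = memberships[memberships["year"] == year] if len(memberships) else memberships
        freq = sub[sub["is_frequent"]] if len(sub) else sub
        frail = sub[sub["is_frail_elderly"]] if len(sub) else sub
        all_calls = int(sub["calls_in_year"].sum()) if len(sub) else 0
        freq_calls = int(freq["calls_in_year"].sum()) if len(freq) else 0
        frail_calls = int(frail["calls_in_year"].sum()) if len(frail) else 0
        rows.append(
            {
                "year": year,
                "all_patients": int(sub["patient_id"].nunique()) if len(sub) else 0,
                "all_calls": all_calls,
                "frequent_users": len(freq),
                "frequent_calls": freq_calls,
                "frequent_calls_pct_of_all": _pct_or_na(freq_calls, all_calls),
                "frail_elderly": len(frail),
                "frail_calls": frail_calls,
                "frail_calls_pct_of_frequent": _pct_or_na(frail_calls, freq_calls),
            }
        )
    per_year = pd.DataFrame(rows)
    totals = pd.Series(
        {
            "all_patients": int(per_year["all_patients"].sum()),
            "all_calls": int(per_year["all_calls"].sum()),
            "frequent_users": int(per_year["frequent_users"].sum()),
            "frequent_calls": int(per_year["frequent_calls"].sum()),
            "frail_elderly": int(per_year["frail_elderly"].sum()),
            "frail_calls": int(per_year["frail_calls"].sum()),
            "all_patients_unique": int(memberships["patient_id"].nunique())
            if len(memberships)
            else 0,
            "frequent_users_unique": int(
                memberships.loc[memberships["is_frequent"], "patient_id"].nunique()
            )
            if len(memberships)
            else 0,
            "frail_elderly_unique": int(
                memberships.loc[memberships["is_frail_elderly"], "patient_id"].nunique()
            )
            if len(memberships)
            else 0,
        }
    )
    return AnnualSummary(per_year=per_year, totals=totals)


def summarize_needs_urgency(
    memberships: pd.DataFrame, params: CohortParams | None = None
) -> AnnualSummary:
    """Needs-and-urgency breakdown for frail elderly users.

    Patient columns count frail-elderly patients with at least one ride of
    the category in the year; because of comorbidity a patient can appear in
    several categories, so patient columns may sum to more than the annual
    total. Call columns are additive: A + B = total and B-DRH + B-other = B.
    """
    params = params or CohortParams()
    frail = (
        memberships[memberships["is_frail_elderly"]]
        if len(memberships)
        else memberships
    )
    years = params.years(memberships["year"].unique() if len(memberships) else [])
    rows = []
    for year in years:
        sub = frail[frail["year"] == year] if len(frail) else frail
        rows.append(
            {
                "year": year,
                "frail_patients_total": len(sub),
                "frail_patients_A": int(sub["has_A_ride"].sum()) if len(sub) else 0,
                "frail_patients_B": int(sub["has_B_ride"].sum()) if len(sub) else 0,
                "frail_patients_B_DRH": int(sub["is_B_DRH"].sum()) if len(sub) else 0,
                "frail_patients_B_other": int(sub["is_B_other"].sum()) if len(sub) else 0,
                "frail_calls_total": int(sub["calls_in_year"].sum()) if len(sub) else 0,
                "frail_calls_A": int(sub["calls_A"].sum()) if len(sub) else 0,
                "frail_calls_B": int(sub["calls_B"].sum()) if len(sub) else 0,
                "frail_calls_B_DRH": int(sub["calls_B_drh"].sum()) if len(sub) else 0,
                "frail_calls_B_other": int(sub["calls_B_other"].sum()) if len(sub) else 0,
            }
        )
    per_year = pd.DataFrame(rows)

    def unique(flag: str) -> int:
        if not len(frail):
            return 0
        return int(frail.loc[frail[flag], "patient_id"].nunique())

    totals = pd.Series(
        {
            **{
                col: int(per_year[col].sum())
                for col in per_year.columns
                if col != "year"
            },
            "frail_patients_total_unique": int(frail["patient_id"].nunique())
            if len(frail)
            else 0,
            "frail_patients_A_unique": unique("has_A_ride"),
            "frail_patients_B_unique": unique("has_B_ride"),
            "frail_patients_B_DRH_unique": unique("is_B_DRH"),
            "frail_patients_B_other_unique": unique("is_B_other"),
        }
    )
    return AnnualSummary(per_year=per_year, totals=totals)
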