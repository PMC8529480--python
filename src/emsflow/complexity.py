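"""Routing-complexity metrics and the low/high dichotomy.

Two archetypal routings motivate the classification. A dialysis "shuttle"
patient ping-pongs between one hospital and a nursing home on a predictable
schedule: few providers, planned rides, a known need — *low* complexity from
the health-care-consumption-uncertainty point of view (these patients are
still frail and resource-intensive). A patient bounced between many
providers and specialties with mixed urgent and planned rides has a routing
nobody fully understands — *high* complexity.

There is no canonical numeric threshold for the dichotomy, so the default
rule here operationalizes the two exemplars — at most ``max_providers_low``
distinct providers *and* some DRH involvement ⇒ low, otherwise high — and is
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .cohorts import CohortParams, classify_drh
from .event_log import UNKNOWN, PatientTrace, RideRecord

__all__ = [
    "ComplexityProfile",
    "ComplexityRule",
    "profile_patient",
    "classify_complexity",
    "cohort_complexity_table",
]


@dataclass(frozen=True)
class ComplexityProfile:
    """Structural metrics of one patient's routing.

    ``provider_entropy`` is the Shannon entropy (bits) of the distribution
    of visits over providers: 0 when a single provider serves the patient,
    at most log2(n_distinct_providers) when visits are spread evenly.
    ``drh_share`` is the fraction of rides that are planned DRH transport.
    """

    patient_id: str
    n_events: int
    n_distinct_providers: int
    n_distinct_specialties: int
    n_distinct_arcs: int
    provider_entropy: float
    drh_share: float
    complexity_class: str | None = None


@dataclass(frozen=True)
class ComplexityRule:
    """Classification rule: low iff few providers and (optionally) DRH need."""

    max_providers_low: int = 2
    require_drh_for_low: bool = True

    def __post_init__(self) -> None:
        if self.max_providers_low < 1:
            raise ValueError("max_providers_low must be >= 1")


def profile_patient(
    trace: PatientTrace,
    drh_classifier: Callable[[RideRecord], bool] | None = None,
    include_unknown: bool = False,
) -> ComplexityProfile:
    """Compute routing metrics for one patient.

    ``"Unknown"`` destinations and specialties are excluded from the distinct
    counts and the visit distribution by default (they are data artifacts,
    not providers); pass ``include_unknown=True`` to keep them. Rides still
    count toward ``n_events`` either way. On-scene treatment (``EMS-S&T``)
    is a provider in its own right.
    """
    if drh_classifier is None:
        params = CohortParams()
        drh_classifier = lambda record: classify_drh(record, params)  # noqa: E731

    providers = [e.destination for e in trace.events]
    specialties = [e.specialty for e in trace.events]
    if not include_unknown:
        providers = [p for p in providers if p != UNKNOWN]
        specialties = [s for s in specialties if s != UNKNOWN]

    counts = pd.Series(providers).value_counts().to_numpy() if providers else np.array([])
    ent = float(_shannon_entropy(counts, base=2)) if counts.size else 0.0

    arc_labels = [p for p in trace.activities() if include_unknown or p != UNKNOWN]
    arcs = set(zip(arc_labels, arc_labels[1:]))

    n_events = len(trace)
    drh_share = sum(1 for e in trace.events if drh_classifier(e)) / n_events
    return ComplexityProfile(
        patient_id=trace.patient_id,
        n_events=n_events,
        n_distinct_providers=len(set(providers)),
        n_distinct_specialties=len(set(specialties)),
        n_distinct_arcs=len(arcs),
        provider_entropy=ent,
        drh_share=drh_share,
    )


def classify_complexity(
    profile: ComplexityProfile, rule: ComplexityRule | None = None
) -> ComplexityProfile:
    """Return the profile with ``complexity_class`` set per the rule."""
    rule = rule or ComplexityRule()
    low = profile.n_distinct_providers <= rule.max_providers_low and (
        not rule.require_drh_for_low or profile.drh_share > 0
    )
    return replace(profile, complexity_class="low" if low else "high")


def cohort_complexity_table(
    profiles: Iterable[ComplexityProfile],
    groups: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Count low/high routings, optionally per group (e.g. per year or stratum).

    ``groups`` maps patient id to a group label; ungrouped cohorts collapse
    to a single ``"all"`` row. Counts partition each group: low + high = total.
    """
    rows = []
    for profile in profiles:
        if profile.complexity_class is None:
            raise ValueError(
                f"profile for {profile.patient_id} is unclassified; "
                "run classify_complexity first"
            )
        group = groups.get(profile.patient_id, "all") if groups else "all"
        rows.append({"group": group, "complexity_class": profile.complexity_class})
    if not rows:
        return pd.DataFrame(columns=["group", "low", "high", "total"])
    frame = pd.DataFrame(rows)
    table = (
        frame.groupby("group")["complexity_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["low", "high"], fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    table["total"] = table["low"] + table["high"]
    return table
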