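"""Frequency-annotated directly-follows process maps over care providers.

A process map is a directed graph whose nodes are activities (care-provider
labels) weighted by how often each was visited, and whose arcs count how
often one activity was *directly followed* by another inside a single
patient's routing. Self-loops are meaningful: two consecutive rides to the
same hospital usually mean the return transport was organized outside the
EMS operator under study, and the map keeps that signal.

Conservation laws tie the map to the log it was mined from: node frequencies
sum to the event count, and arc frequencies sum to ``events - cases`` because
a trace of length L contributes exactly L - 1 directly-follows pairs.
Filtered maps are *views* — elements below the thresholds are removed and
surviving frequencies are left untouched, so the laws intentionally no longer
hold; the originals stay available in provenance.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .event_log import PatientTrace, activity_label

__all__ = [
    "ProcessMap",
    "MapFilterSpec",
    "MapDiff",
    "mine_dfg",
    "filter_map",
    "diff_maps",
    "export_dot",
]

Arc = tuple[str, str]


@dataclass
class ProcessMap:
    """A directly-follows graph with event, arc, start and end frequencies."""

    nodes: dict[str, int]
    arcs: dict[Arc, int]
    case_count: int
    event_count: int
    start_counts: dict[str, int]
    end_counts: dict[str, int]
    provenance: dict = field(default_factory=dict)

    @property
    def is_filtered(self) -> bool:
        return bool(self.provenance.get("filtered"))

    def validate(self) -> None:
        """Check the conservation laws (meaningful for unfiltered maps only)."""
        if self.is_filtered:
            return
        if sum(self.nodes.values()) != self.event_count:
            raise AssertionError("node frequencies must sum to event_count")
        if sum(self.arcs.values()) != self.event_count - self.case_count:
            raise AssertionError("arc frequencies must sum to events - cases")
        if sum(self.start_counts.values()) != self.case_count:
            raise AssertionError("start counts must sum to case_count")
        if sum(self.end_counts.values()) != self.case_count:
            raise AssertionError("end counts must sum to case_count")

    def to_json(self, path: str | Path | None = None) -> str:
        """Deterministic JSON serialization (arcs keyed ``source -> target``)."""
        payload = {
            "nodes": dict(sorted(self.nodes.items())),
            "arcs": {
                f"{s} -> {t}": n for (s, t), n in sorted(self.arcs.items())
            },
            "case_count": self.case_count,
            "event_count": self.event_count,
            "start_counts": dict(sorted(self.start_counts.items())),
            "end_counts": dict(sorted(self.end_counts.items())),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ProcessMap":
        raw = json.loads(text)
        arcs = {}
        for key, n in raw["arcs"].items():
            source, target = key.split(" -> ", 1)
            arcs[(source, target)] = n
        return cls(
            nodes=raw["nodes"],
            arcs=arcs,
            case_count=raw["case_count"],
            event_count=raw["event_count"],
            start_counts=raw["start_counts"],
            end_counts=raw["end_counts"],
            provenance=raw.get("provenance", {}),
        )


@dataclass(frozen=True)
class MapFilterSpec:
    """Node/arc frequency thresholds used before rendering busy maps."""

    min_node_freq: int = 0
    min_arc_freq: int = 0

    def __post_init__(self) -> None:
        if self.min_node_freq < 0 or self.min_arc_freq < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class MapDiff:
    """Arc/node-level comparison of an earlier and a later map.

    ``arcs_added`` are present only in the later map (drawn red: new
    connections between providers); ``arcs_removed`` only in the earlier map
    (drawn green: connections that disappeared). ``frequency_deltas`` gives
    later minus earlier for arcs present in both.
    """

    arcs_added: frozenset[Arc]
    arcs_removed: frozenset[Arc]
    nodes_added: frozenset[str]
    nodes_removed: frozenset[str]
    frequency_deltas: Mapping[Arc, int]

    def __post_init__(self) -> None:
        if self.arcs_added & self.arcs_removed:
            raise ValueError("an arc cannot be both added and removed")

    @property
    def is_empty(self) -> bool:
        return not (
            self.arcs_added
            or self.arcs_removed
            or self.nodes_added
            or self.nodes_removed
            or any(self.frequency_deltas.values())
        )


def mine_dfg(
    traces: Sequence[PatientTrace],
    activity_field: str = "destination",
    exclude: Iterable[str] = (),
) -> ProcessMap:
    """Mine the directly-follows graph of a trace collection.

    ``activity_field`` selects the label granularity (provider only, or
    provider + specialty). ``exclude`` removes activity labels from the
    routings before mining (a trace left empty by the exclusion no longer
    counts as a case); by default nothing is excluded — ``"Unknown"`` and
    ``"EMS-S&T"`` are first-class activities.
    """
    if not traces:
        raise ValueError("cannot mine an empty trace collection")
    excluded = set(exclude)
    nodes: Counter = Counter()
    arcs: Counter = Counter()
    starts: Counter = Counter()
    ends: Counter = Counter()
    cases = events = 0
    for trace in traces:
        labels = [
            lab for lab in trace.activities(activity_field) if lab not in excluded
        ]
        if not labels:
            continue
        cases += 1
        events += len(labels)
        nodes.update(labels)
        starts[labels[0]] += 1
        ends[labels[-1]] += 1
        for source, target in zip(labels, labels[1:]):
            arcs[(source, target)] += 1
    if cases == 0:
        raise ValueError("exclusion list removed every event from every trace")
    pm = ProcessMap(
        nodes=dict(nodes),
        arcs=dict(arcs),
        case_count=cases,
        event_count=events,
        start_counts=dict(starts),
        end_counts=dict(ends),
        provenance={"activity_field": activity_field, "excluded": sorted(excluded)},
    )
    pm.validate()
    return pm


def filter_map(pm: ProcessMap, spec: MapFilterSpec) -> ProcessMap:
    """Drop nodes below ``min_node_freq`` and arcs below ``min_arc_freq``.

    An arc is also dropped when either endpoint was dropped. Surviving
    frequencies are unchanged; the result is a view whose provenance records
    the thresholds and the original totals.
    """
    keep_nodes = {
        label: n for label, n in pm.nodes.items() if n >= spec.min_node_freq
    }
    keep_arcs = {
        (s, t): n
        for (s, t), n in pm.arcs.items()
        if n >= spec.min_arc_freq and s in keep_nodes and t in keep_nodes
    }
    provenance = dict(pm.provenance)
    provenance.update(
        {
            "filtered": True,
            "min_node_freq": spec.min_node_freq,
            "min_arc_freq": spec.min_arc_freq,
            "original_event_count": pm.provenance.get(
                "original_event_count", pm.event_count
            ),
            "original_case_count": pm.provenance.get(
                "original_case_count", pm.case_count
            ),
        }
    )
    return ProcessMap(
        nodes=keep_nodes,
        arcs=keep_arcs,
        case_count=pm.case_count,
        event_count=pm.event_count,
        start_counts={k: v for k, v in pm.start_counts.items() if k in keep_nodes},
        end_counts={k: v for k, v in pm.end_counts.items() if k in keep_nodes},
        provenance=provenance,
    )


def diff_maps(earlier: ProcessMap, later: ProcessMap) -> MapDiff:
    """Partition arcs into added / removed / shared-with-delta."""
    earlier_arcs, later_arcs = set(earlier.arcs), set(later.arcs)
    shared = earlier_arcs & later_arcs
    return MapDiff(
        arcs_added=frozenset(later_arcs - earlier_arcs),
        arcs_removed=frozenset(earlier_arcs - later_arcs),
        nodes_added=frozenset(set(later.nodes) - set(earlier.nodes)),
        nodes_removed=frozenset(set(earlier.nodes) - set(later.nodes)),
        frequency_deltas={
            arc: later.arcs[arc] - earlier.arcs[arc] for arc in sorted(shared)
        },
    )


def _dot_id(label: str) -> str:
    return '"' + label.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_dot(
    pm: ProcessMap,
    diff: MapDiff | None = None,
    style: Mapping[str, str] | None = None,
) -> str:
    """Render a map as deterministic DOT text.

    Nodes are labelled ``"name (frequency)"`` and edges with their
    frequency. When a diff is supplied, arcs newly appeared (``arcs_added``)
    are drawn red and arcs that later disappear (``arcs_removed``) green —
    matching the convention of highlighting new connections on the later
    map and vanishing ones on the earlier map.
    """
    style = dict(style or {})
    added = diff.arcs_added if diff else frozenset()
    removed = diff.arcs_removed if diff else frozenset()
    lines = ["digraph process_map {"]
    lines.append(f'  rankdir={style.get("rankdir", "TB")};')
    lines.append('  node [shape=box, style="rounded,filled", fillcolor="#E8F0FE"];')
    for label in sorted(pm.nodes):
        lines.append(
            f'  {_dot_id(label)} [label="{label} ({pm.nodes[label]})"];'
        )
    for (source, target) in sorted(pm.arcs):
        n = pm.arcs[(source, target)]
        attrs = [f'label="{n}"']
        if (source, target) in added:
            attrs.append('color="red"')
        elif (source, target) in removed:
            attrs.append('color="green"')
        lines.append(
            f"  {_dot_id(source)} -> {_dot_id(target)} [{', '.join(attrs)}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
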