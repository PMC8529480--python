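"""Reading, cleaning and ordering ambulance-ride records into patient traces.

The unit of observation is a single ambulance ride: a timestamped transport of
one patient to a destination (a hospital, a nursing home, on-scene treatment by
the crew, or unknown) with an urgency code and a requested medical specialty.
A patient's time-ordered sequence of rides is their *routing* — the trace that
every downstream analysis (cohort identification, process-map mining,
complexity scoring) consumes.

Cleaning follows administrative-record practice: rides not linked to a patient
identifier are dropped (and counted), and a missing destination is replaced by
the literal activity label ``"Unknown"`` rather than discarded, because the
ride itself still happened and still counts toward utilization.
"""

from __future__ import annotations

import csv
import hashlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

__all__ = [
    "URGENCY_CODES",
    "UNKNOWN",
    "RideRecord",
    "Provenance",
    "EventLog",
    "PatientTrace",
    "CleaningReport",
    "SchemaConfig",
    "SchemaError",
    "ContractError",
    "read_rides",
    "clean_log",
    "build_traces",
    "events_in_year",
    "traces_for_year",
    "write_log",
    "read_xes",
]

#: The three urgency codes used by Dutch EMS dispatch: A1 and A2 are urgent
#: rides (with and without the strictest response-time norm), B is planned
#: transport legitimized by a health-care need prohibiting self-transport.
URGENCY_CODES = frozenset({"A1", "A2", "B"})

#: Canonical label substituted for a missing destination or specialty.
UNKNOWN = "Unknown"


class SchemaError(ValueError):
    """A column mapping refers to a column the input file does not have."""


class ContractError(ValueError):
    """An operation was called on data that violates its precondition."""


@dataclass(frozen=True)
class RideRecord:
    """One ambulance ride.

    Parameters
    ----------
    timestamp : datetime
        Local calendar instant of the ride, second resolution.
    urgency : str
        One of ``A1``, ``A2`` (urgent) or ``B`` (planned).
    destination : str
        Care-provider activity label, e.g. ``"RegHospital 1-dialysis"``,
        ``"Nursing home"``, ``"EMS-S&T"`` or ``"Unknown"``.
    specialty : str
        Medical specialty requested, free text; ``"Unknown"`` if absent.
    patient_id : str or None
        Opaque patient identifier; ``None`` for orphan records that cleaning
        will drop.
    age : int or None
        Patient age in whole years at the time of the ride, if recorded.
    seq : int
        Zero-based position of the row in the source file; used as a stable
        tie-break when two rides share a timestamp.
    """

    timestamp: datetime
    urgency: str
    destination: str
    specialty: str = UNKNOWN
    patient_id: str | None = None
    age: int | None = None
    seq: int = 0

    def __post_init__(self) -> None:
        if self.urgency not in URGENCY_CODES:
            raise ValueError(
                f"urgency must be one of {sorted(URGENCY_CODES)}, got {self.urgency!r}"
            )
        if self.age is not None and self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")

    @property
    def urgency_class(self) -> str:
        """Coarse urgency class: ``"A"`` for A1/A2, ``"B"`` for B."""
        return "A" if self.urgency in ("A1", "A2") else "B"

    @property
    def year(self) -> int:
        return self.timestamp.year


@dataclass
class Provenance:
    """Where a log came from and what happened to it on the way in."""

    source: str = "<memory>"
    rows_read: int = 0
    rows_rejected_bad_timestamp: int = 0
    rows_dropped_no_patient: int = 0
    destinations_marked_unknown: int = 0
    cleaned: bool = False
    notes: dict = field(default_factory=dict)


@dataclass
class EventLog:
    """An ordered collection of ride records plus ingest provenance."""

    records: list[RideRecord]
    provenance: Provenance = field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RideRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the log (one row per ride)."""
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "timestamp": [r.timestamp for r in self.records],
                "urgency": [r.urgency for r in self.records],
                "destination": [r.destination for r in self.records],
                "specialty": [r.specialty for r in self.records],
                "age": pd.array([r.age for r in self.records], dtype="Int64"),
            }
        )


@dataclass(frozen=True)
class PatientTrace:
    """A patient's routing: their rides in non-decreasing time order."""

    patient_id: str
    events: tuple[RideRecord, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a trace must contain at least one event")
        if any(e.patient_id != self.patient_id for e in self.events):
            raise ValueError("all events in a trace must share the patient_id")
        times = [e.timestamp for e in self.events]
        if any(a > b for a, b in zip(times, times[1:])):
            raise ValueError("trace events must be in non-decreasing time order")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[RideRecord]:
        return iter(self.events)

    @property
    def span(self) -> tuple:
        """(date of first ride, date of last ride)."""
        return (self.events[0].timestamp.date(), self.events[-1].timestamp.date())

    def activities(self, field: str = "destination") -> list[str]:
        """The trace's activity-label sequence (see :func:`activity_label`)."""
        return [activity_label(e, field) for e in self.events]


@dataclass(frozen=True)
class CleaningReport:
    """Counts produced by :func:`clean_log`; conservation always holds."""

    rows_read: int
    rows_dropped_no_patient: int
    destinations_marked_unknown: int
    rows_rejected_bad_timestamp: int

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    @property
    def rows_retained(self) -> int:
        return (
            self.rows_read
            - self.rows_dropped_no_patient
            - self.rows_rejected_bad_timestamp
        )


# ---------------------------------------------------------------------------
# Schema / column mapping
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "date": "date",
    "time": "time",
    "urgency": "urgency",
    "destination": "destination",
    "specialty": "specialty",
    "age": "age",
}

_MANDATORY_FIELDS = ("date", "urgency", "destination")


@dataclass
class SchemaConfig:
    """Column mapping and parsing dialect for delimited ride files.

    The canonical dialect is ISO dates (``YYYY-MM-DD``) in a ``date`` column
    and ``HH:MM:SS`` in a ``time`` column; a single combined ``timestamp``
    column can be declared instead by mapping ``date`` to it and setting
    ``time`` to ``None``. ``aliases`` optionally maps raw destination labels
    to canonical ones (e.g. collapsing service-tagged labels like
    ``"RegHospital 1-dialysis"`` onto the provider ``"RegHospital 1"``).
    """

    columns: dict[str, str | None] = field(
        default_factory=lambda: dict(_DEFAULT_COLUMNS)
    )
    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    time_format: str = "%H:%M:%S"
    aliases: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        columns = dict(_DEFAULT_COLUMNS)
        columns.update(raw.get("columns", {}))
        cfg.columns = columns
        for key in ("delimiter", "date_format", "time_format"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.aliases = dict(raw.get("aliases", {}))
        return cfg


def activity_label(record: RideRecord, field: str = "destination") -> str:
    """Map a ride to its process-map activity label.

    ``"destination"`` uses the provider label alone; ``"destination_specialty"``
    appends the specialty, the finer granularity used when the same provider
    offers distinguishable services.
    """
    if field == "destination":
        return record.destination
    if field == "destination_specialty":
        return f"{record.destination} ({record.specialty})"
    raise ValueError(f"unknown activity field {field!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _parse_timestamp(
    date_text: str, time_text: str | None, schema: SchemaConfig
) -> datetime | None:
    date_text = (date_text or "").strip()
    if not date_text:
        return None
    fmt = schema.date_format
    if time_text is not None:
        date_text = f"{date_text} {time_text.strip() or '00:00:00'}"
        fmt = f"{schema.date_format} {schema.time_format}"
    try:
        return datetime.strptime(date_text, fmt)
    except ValueError:
        return None


def _hash_id(patient_id: str) -> str:
    return hashlib.sha256(patient_id.encode()).hexdigest()[:12]


def read_rides(
    path, schema: SchemaConfig | None = None, anonymize: bool = False
) -> EventLog:
    """Read a delimited ride file into an :class:`EventLog`.

    ``path`` may be a filesystem path or an open text handle. Rows whose
    timestamp does not parse to a real calendar instant are rejected and
    counted in provenance; everything else is kept verbatim (cleaning is a
    separate, explicit step). Input row order is preserved and recorded in
    each record's ``seq``.

    Raises
    ------
    SchemaError
        If a mapped column is missing from the file.
    """
    schema = schema or SchemaConfig()
    frame = pd.read_csv(
        path, sep=schema.delimiter, dtype=str, keep_default_na=False, engine="python"
    )

    for fld in _MANDATORY_FIELDS:
        col = schema.columns.get(fld)
        if col is None or col not in frame.columns:
            raise SchemaError(f"mandatory column for field {fld!r} ({col!r}) not found")

    def col(fld: str) -> str | None:
        name = schema.columns.get(fld)
        return name if name is not None and name in frame.columns else None

    time_col = col("time")
    pid_col, spec_col, age_col = col("patient_id"), col("specialty"), col("age")

    records: list[RideRecord] = []
    rejected = 0
    for seq, row in enumerate(frame.to_dict(orient="records")):
        ts = _parse_timestamp(
            row[schema.columns["date"]],
            row[time_col] if time_col else None,
            schema,
        )
        if ts is None:
            rejected += 1
            continue
        pid = (row[pid_col].strip() or None) if pid_col else None
        if pid is not None and anonymize:
            pid = _hash_id(pid)
        age_text = (row[age_col].strip() if age_col else "") or ""
        age = int(age_text) if age_text else None
        destination = row[schema.columns["destination"]].strip()
        destination = schema.aliases.get(destination, destination)
        records.append(
            RideRecord(
                timestamp=ts,
                urgency=row[schema.columns["urgency"]].strip(),
                destination=destination,
                specialty=(row[spec_col].strip() if spec_col else "") or UNKNOWN,
                patient_id=pid,
                age=age,
                seq=seq,
            )
        )

    provenance = Provenance(
        source=str(getattr(path, "name", path)),
        rows_read=len(frame),
        rows_rejected_bad_timestamp=rejected,
    )
    return EventLog(records=records, provenance=provenance)


def clean_log(log: EventLog) -> tuple[EventLog, CleaningReport]:
    """Drop orphan records and fill missing labels; total and idempotent.

    Records without a patient identifier cannot be assigned to a routing and
    are removed; empty destinations and specialties become ``"Unknown"``.
    Counts are cumulative across repeated cleaning, so cleaning an already
    clean log changes nothing and reports the same numbers.
    """
    kept: list[RideRecord] = []
    dropped = marked = 0
    for record in log.records:
        if record.patient_id is None:
            dropped += 1
            continue
        changes = {}
        if not record.destination:
            changes["destination"] = UNKNOWN
            marked += 1
        if not record.specialty:
            changes["specialty"] = UNKNOWN
        kept.append(replace(record, **changes) if changes else record)

    prov = replace(
        log.provenance,
        rows_dropped_no_patient=log.provenance.rows_dropped_no_patient + dropped,
        destinations_marked_unknown=log.provenance.destinations_marked_unknown + marked,
        cleaned=True,
    )
    report = CleaningReport(
        rows_read=prov.rows_read,
        rows_dropped_no_patient=prov.rows_dropped_no_patient,
        destinations_marked_unknown=prov.destinations_marked_unknown,
        rows_rejected_bad_timestamp=prov.rows_rejected_bad_timestamp,
    )
    return EventLog(records=kept, provenance=prov), report


def build_traces(log: EventLog) -> list[PatientTrace]:
    """Partition a cleaned log into one time-ordered trace per patient.

    Events are sorted by timestamp ascending; ties keep stable input order
    (the ``seq`` recorded at read time). Traces are returned sorted by
    patient id for determinism.

    Raises
    ------
    ContractError
        If any record lacks a patient id (the log was not cleaned).
    """
    by_patient: dict[str, list[RideRecord]] = {}
    for record in log.records:
        if record.patient_id is None:
            raise ContractError(
                "log contains records without patient_id; run clean_log first"
            )
        by_patient.setdefault(record.patient_id, []).append(record)
    traces = []
    for pid in sorted(by_patient):
        events = sorted(by_patient[pid], key=lambda e: (e.timestamp, e.seq))
        traces.append(PatientTrace(patient_id=pid, events=tuple(events)))
    return traces


def events_in_year(trace: PatientTrace, year: int) -> PatientTrace | None:
    """The within-year sub-trace, or None if the patient had no ride that year."""
    events = tuple(e for e in trace.events if e.year == year)
    if not events:
        return None
    return PatientTrace(patient_id=trace.patient_id, events=events)


def traces_for_year(
    traces: Iterable[PatientTrace], year: int
) -> list[PatientTrace]:
    """Restrict a trace collection to one calendar year, dropping empty traces."""
    out = []
    for trace in traces:
        sub = events_in_year(trace, year)
        if sub is not None:
            out.append(sub)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_XES_NS = "http://www.xes-standard.org/"


def _records_of(obj: EventLog | Sequence[PatientTrace]) -> list[RideRecord]:
    if isinstance(obj, EventLog):
        return list(obj.records)
    return [e for trace in obj for e in trace.events]


def write_log(
    obj: EventLog | Sequence[PatientTrace],
    path: str | Path,
    format: str = "delimited",
) -> None:
    """Serialize a log or trace collection.

    ``delimited`` writes the canonical CSV dialect that :func:`read_rides`
    reads back field-for-field. ``xes`` writes the process-mining event-log
    interchange format, one ``<trace>`` per patient with ``concept:name`` set
    to the destination and ride attributes carried as event attributes.
    """
    path = Path(path)
    if format == "delimited":
        _write_delimited(_records_of(obj), path)
    elif format == "xes":
        traces = obj if not isinstance(obj, EventLog) else build_traces(obj)
        _write_xes(traces, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_delimited(records: Sequence[RideRecord], path: Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["patient_id", "date", "time", "urgency", "destination", "specialty", "age"]
        )
        for r in records:
            writer.writerow(
                [
                    r.patient_id or "",
                    r.timestamp.strftime("%Y-%m-%d"),
                    r.timestamp.strftime("%H:%M:%S"),
                    r.urgency,
                    r.destination,
                    r.specialty,
                    "" if r.age is None else r.age,
                ]
            )


def _write_xes(traces: Sequence[PatientTrace], path: Path) -> None:
    root = ET.Element("log", attrib={"xes.version": "1.0", "xmlns": _XES_NS})
    for trace in traces:
        trace_el = ET.SubElement(root, "trace")
        ET.SubElement(
            trace_el, "string", attrib={"key": "concept:name", "value": trace.patient_id}
        )
        for event in trace.events:
            ev = ET.SubElement(trace_el, "event")
            ET.SubElement(
                ev, "string", attrib={"key": "concept:name", "value": event.destination}
            )
            ET.SubElement(
                ev,
                "date",
                attrib={
                    "key": "time:timestamp",
                    "value": event.timestamp.isoformat(),
                },
            )
            ET.SubElement(ev, "string", attrib={"key": "urgency", "value": event.urgency})
            ET.SubElement(
                ev, "string", attrib={"key": "specialty", "value": event.specialty}
            )
            if event.age is not None:
                ET.SubElement(
                    ev, "int", attrib={"key": "age", "value": str(event.age)}
                )
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_xes(path: str | Path) -> list[PatientTrace]:
    """Read traces back from an XES file written by :func:`write_log`."""
    root = ET.parse(path).getroot()
    ns = {"x": _XES_NS} if root.tag.startswith("{") else {}
    prefix = "x:" if ns else ""
    traces = []
    for seq_base, trace_el in enumerate(root.findall(f"{prefix}trace", ns)):
        pid = None
        for attr in trace_el.findall(f"{prefix}string", ns):
            if attr.get("key") == "concept:name":
                pid = attr.get("value")
        events = []
        for i, ev in enumerate(trace_el.findall(f"{prefix}event", ns)):
            attrs = {
                el.get("key"): el.get("value")
                for el in ev
            }
            events.append(
                RideRecord(
                    timestamp=datetime.fromisoformat(attrs["time:timestamp"]),
                    urgency=attrs["urgency"],
                    destination=attrs["concept:name"],
                    specialty=attrs.get("specialty", UNKNOWN),
                    patient_id=pid,
                    age=int(attrs["age"]) if "age" in attrs else None,
                    seq=i,
                )
            )
        traces.append(PatientTrace(patient_id=pid, events=tuple(events)))
    return traces
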