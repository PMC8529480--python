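"""Synthetic EMS ride-log generator with ground-truth sidecars.

Real EMS records are confidential, so the pipeline is exercised on simulated
logs built from four patient archetypes observed in regional EMS data:

``drh_shuttle``
    A frail patient on a predictable treatment schedule (dialysis, radiation
    therapy or hyperbaric medicine): planned (B) rides every few days that
    shuttle between one hospital and a nursing home. Occasionally one leg of
    the round trip is organized outside the EMS operator, which is what
    produces the characteristic self-loops in the mined map.
``chaotic_frail``
    A frail patient with diverse needs served by several providers in mixed
    urgent/planned rides — the high-complexity archetype. Constructed with at
    least 4 rides spanning at least 3 distinct providers so that the planted
    complexity label is recoverable by the default classification rule.
``episodic``
    A middle-aged patient with a handful of rides in one year.
``one_off``
    A single ride.

Patients are recruited per calendar year; recruitment grows at the
background EMS transport growth rate (default 5.1 %/year) and the
``chaotic_frail`` archetype is additionally multiplied by a policy-shock
factor from a shock year onward, emulating the surge in high-complexity
frail elderly users after long-term-care reform. All randomness flows
through one seeded NumPy generator, so a config + seed pair reproduces the
log byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np

from .event_log import EventLog, Provenance, RideRecord

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_archetypes",
    "generate_log",
    "corrupt_log",
]

_PROVIDERS = [
    "Hospital A",
    "Hospital D",
    "RegHospital 1",
    "RegHospital 2",
    "RegHospital 3",
    "RegHospital 4",
    "Nursing home",
    "EMS-S&T",
]
_SPECIALTIES = [
    "Other specialties",
    "Pulmonology",
    "Internal medicine",
    "Surgery",
    "General",
    "Cardiology",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one patient archetype.

    ``call_process`` is ``"periodic"`` (treatments every ``interval_days``
    ± ``jitter_days``, each usually followed by a return ride) or
    ``"poisson"`` (``annual_call_rate`` rides scattered uniformly over the
    year). ``urgency_mix`` gives probabilities over (A1, A2, B);
    ``age_distribution`` is (min, max, mode) in years, sampled triangularly.
    """

    name: str
    annual_call_rate: float
    call_process: str = "poisson"
    interval_days: float = 3.0
    jitter_days: float = 1.0
    missing_leg_prob: float = 0.15
    urgency_mix: tuple[float, float, float] = (0.3, 0.3, 0.4)
    provider_pool_size: int = 6
    specialty_pool: tuple[str, ...] = tuple(_SPECIALTIES)
    age_distribution: tuple[int, int, int] = (18, 95, 60)
    min_calls: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.urgency_mix) - 1.0) > 1e-9:
            raise ValueError("urgency_mix probabilities must sum to 1")
        if self.name != "one_off" and self.annual_call_rate <= 0:
            raise ValueError("annual_call_rate must be > 0")
        if self.call_process not in ("periodic", "poisson"):
            raise ValueError("call_process must be 'periodic' or 'poisson'")


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """The four stock archetypes (see module docstring)."""
    return {
        "drh_shuttle": ArchetypeSpec(
            name="drh_shuttle",
            annual_call_rate=100.0,  # implied by the periodic process
            call_process="periodic",
            interval_days=3.0,
            jitter_days=1.0,
            missing_leg_prob=0.15,
            urgency_mix=(0.0, 0.0, 1.0),
            provider_pool_size=1,
            specialty_pool=("Other specialties", "Internal medicine"),
            age_distribution=(70, 92, 78),
        ),
        "chaotic_frail": ArchetypeSpec(
            name="chaotic_frail",
            annual_call_rate=8.0,
            call_process="poisson",
            urgency_mix=(0.3, 0.25, 0.45),
            provider_pool_size=6,
            age_distribution=(70, 95, 82),
            min_calls=4,
        ),
        "episodic": ArchetypeSpec(
            name="episodic",
            annual_call_rate=2.5,
            call_process="poisson",
            urgency_mix=(0.35, 0.35, 0.3),
            provider_pool_size=3,
            age_distribution=(40, 85, 65),
        ),
        "one_off": ArchetypeSpec(
            name="one_off",
            annual_call_rate=1.0,
            call_process="poisson",
            urgency_mix=(0.5, 0.3, 0.2),
            provider_pool_size=1,
            age_distribution=(18, 95, 55),
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator parameters; ``seed`` is mandatory for reproducibility."""

    seed: int
    years: tuple[int, int] = (2012, 2017)
    n_patients_per_archetype: Mapping[str, int] = field(
        default_factory=lambda: {
            "drh_shuttle": 15,
            "chaotic_frail": 40,
            "episodic": 120,
            "one_off": 320,
        }
    )
    background_growth_rate: float = 0.051
    policy_shock: float = 2.0
    policy_shock_year: int = 2014
    missing_destination_rate: float = 0.0
    orphan_record_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.years[0] > self.years[1]:
            raise ValueError("years range must be non-empty")
        if not self.n_patients_per_archetype or not any(
            self.n_patients_per_archetype.values()
        ):
            raise ValueError("archetype mix must recruit at least one patient")
        for rate_name in ("missing_destination_rate", "orphan_record_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1]")
        if self.background_growth_rate < 0 or self.policy_shock < 0:
            raise ValueError("growth and shock multipliers must be >= 0")


@dataclass
class GroundTruth:
    """The planted truth behind a generated log.

    ``archetype`` maps patient id to archetype name; ``calls_per_year`` maps
    ``(patient_id, year)`` to the ride count actually emitted;
    ``frequent_by_year`` and ``drh_by_year`` hold the planted cohort
    memberships (threshold 4 rides/year; DRH = at least one planned DRH
    ride); ``records_per_year`` the emitted volume per year.
    """

    threshold: int
    archetype: dict[str, str]
    calls_per_year: dict[tuple[str, int], int]
    frequent_by_year: dict[int, set[str]]
    drh_by_year: dict[int, set[str]]
    records_per_year: dict[int, int]

    def complexity_label(self, patient_id: str) -> str:
        """The planted low/high complexity label implied by the archetype."""
        return "low" if self.archetype[patient_id] == "drh_shuttle" else "high"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "archetype": self.archetype,
            "calls_per_year": {
                f"{pid}:{year}": n for (pid, year), n in self.calls_per_year.items()
            },
            "frequent_by_year": {
                str(y): sorted(s) for y, s in self.frequent_by_year.items()
            },
            "drh_by_year": {str(y): sorted(s) for y, s in self.drh_by_year.items()},
            "records_per_year": {str(y): n for y, n in self.records_per_year.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sample_age(rng: np.random.Generator, dist: tuple[int, int, int]) -> int:
    lo, hi, mode = dist
    return int(round(rng.triangular(lo, mode, hi)))


def _year_instant(rng: np.random.Generator, year: int) -> datetime:
    start = datetime(year, 1, 1)
    n_days = (datetime(year + 1, 1, 1) - start).days
    return start + timedelta(
        days=int(rng.integers(n_days)), seconds=int(rng.integers(86400))
    )


def _periodic_rides(
    rng: np.random.Generator, spec: ArchetypeSpec, year: int, hospital: str
) -> list[tuple[datetime, str, str, str]]:
    """Treatment shuttle: hospital visit + (usually) a same-day return ride."""
    rides = []
    day = float(rng.uniform(0, spec.interval_days))
    year_days = (datetime(year + 1, 1, 1) - datetime(year, 1, 1)).days
    specialty = str(rng.choice(spec.specialty_pool))
    while day < year_days - 1:
        out_time = datetime(year, 1, 1) + timedelta(
            days=int(day), seconds=int(rng.integers(8 * 3600, 12 * 3600))
        )
        if rng.random() >= spec.missing_leg_prob:
            rides.append((out_time, "B", hospital, specialty))
        if rng.random() >= spec.missing_leg_prob:
            back_time = out_time + timedelta(seconds=int(rng.integers(3600, 6 * 3600)))
            rides.append((back_time, "B", "Nursing home", specialty))
        day += float(
            rng.uniform(
                max(0.5, spec.interval_days - spec.jitter_days),
                spec.interval_days + spec.jitter_days,
            )
        )
    return rides


def _poisson_rides(
    rng: np.random.Generator, spec: ArchetypeSpec, year: int
) -> list[tuple[datetime, str, str, str]]:
    if spec.name == "one_off":
        n = 1
    else:
        n = max(int(rng.poisson(spec.annual_call_rate)), spec.min_calls)
        if n == 0:
            return []
    pool = list(rng.choice(_PROVIDERS, size=spec.provider_pool_size, replace=False))
    urgencies = rng.choice(["A1", "A2", "B"], size=n, p=spec.urgency_mix)
    # Force distinct providers on the first rides so a multi-provider
    # archetype cannot degenerate to a one-provider routing by chance.
    n_forced = min(len(pool), n) if spec.min_calls else 0
    providers = list(rng.permutation(pool))[:n_forced] + [
        str(rng.choice(pool)) for _ in range(n - n_forced)
    ]
    rides = []
    for i in range(n):
        rides.append(
            (
                _year_instant(rng, year),
                str(urgencies[i]),
                str(providers[i]),
                str(rng.choice(spec.specialty_pool)),
            )
        )
    return rides


def generate_log(
    config: SimulationConfig,
    archetypes: Mapping[str, ArchetypeSpec] | None = None,
    threshold: int = 4,
) -> tuple[EventLog, GroundTruth]:
    """Generate a clean synthetic log and its ground-truth sidecar.

    Deterministic given ``config.seed``. Every record carries a patient id
    and a destination; use :func:`corrupt_log` to inject the orphan records
    and missing destinations that cleaning must handle.
    """
    archetypes = dict(archetypes or default_archetypes())
    rng = np.random.default_rng(config.seed)
    first_year, last_year = config.years

    truth = GroundTruth(
        threshold=threshold,
        archetype={},
        calls_per_year={},
        frequent_by_year={y: set() for y in range(first_year, last_year + 1)},
        drh_by_year={y: set() for y in range(first_year, last_year + 1)},
        records_per_year={y: 0 for y in range(first_year, last_year + 1)},
    )
    raw: list[tuple[datetime, str, str, str, str, int]] = []

    for year in range(first_year, last_year + 1):
        growth = (1.0 + config.background_growth_rate) ** (year - first_year)
        for name, base_n in sorted(config.n_patients_per_archetype.items()):
            if name not in archetypes:
                raise ValueError(f"no ArchetypeSpec for archetype {name!r}")
            spec = archetypes[name]
            n = base_n * growth
            if name == "chaotic_frail" and year >= config.policy_shock_year:
                n *= config.policy_shock
            n = int(round(n))
            for i in range(n):
                pid = f"{name}-{year}-{i:04d}"
                age = _sample_age(rng, spec.age_distribution)
                if spec.call_process == "periodic":
                    hospital = f"RegHospital {1 + int(rng.integers(4))}-dialysis"
                    rides = _periodic_rides(rng, spec, year, hospital)
                else:
                    rides = _poisson_rides(rng, spec, year)
                if not rides:
                    continue
                truth.archetype[pid] = name
                truth.calls_per_year[(pid, year)] = len(rides)
                truth.records_per_year[year] += len(rides)
                if len(rides) >= threshold:
                    truth.frequent_by_year[year].add(pid)
                if any(
                    urgency == "B"
                    and any(k in dest.lower() for k in ("dialysis", "radiation", "hyperbaric"))
                    for _, urgency, dest, _ in rides
                ):
                    truth.drh_by_year[year].add(pid)
                for ts, urgency, dest, specialty in rides:
                    raw.append((ts, urgency, dest, specialty, pid, age))

    raw.sort(key=lambda r: (r[0], r[4]))
    records = [
        RideRecord(
            timestamp=ts,
            urgency=urgency,
            destination=dest,
            specialty=specialty,
            patient_id=pid,
            age=age,
            seq=seq,
        )
        for seq, (ts, urgency, dest, specialty, pid, age) in enumerate(raw)
    ]
    log = EventLog(
        records=records,
        provenance=Provenance(
            source=f"simulated(seed={config.seed})", rows_read=len(records)
        ),
    )
    return log, truth


def corrupt_log(log: EventLog, config: SimulationConfig) -> EventLog:
    """Inject exactly the configured fractions of orphan / blank-destination rows.

    ``round(rate * n)`` records lose their patient id (orphans) and a
    disjoint ``round(rate * n)`` records get a blanked destination, chosen by
    seeded sampling, so the injected counts can be compared one-to-one with
    the cleaning report afterwards. Counts are recorded in
    ``provenance.notes``.
    """
    n = len(log.records)
    k_orphan = int(round(config.orphan_record_rate * n))
    k_missing = int(round(config.missing_destination_rate * n))
    if k_orphan + k_missing > n:
        raise ValueError("corruption rates exceed the available records")
    rng = np.random.default_rng((config.seed * 2654435761 + 1) % 2**31)
    chosen = rng.choice(n, size=k_orphan + k_missing, replace=False)
    orphans = set(int(i) for i in chosen[:k_orphan])
    missing = set(int(i) for i in chosen[k_orphan:])

    records = []
    for i, record in enumerate(log.records):
        if i in orphans:
            record = replace(record, patient_id=None)
        elif i in missing:
            record = replace(record, destination="")
        records.append(record)
    prov = replace(
        log.provenance,
        notes={
            **log.provenance.notes,
            "injected_orphans": k_orphan,
            "injected_missing_destinations": k_missing,
        },
    )
    return EventLog(records=records, provenance=prov)
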