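"""Shared fixtures: toy logs, the worked-example routings, and a small
deterministic synthetic cohort."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

import emsflow as ef
from emsflow import datasets


def make_record(
    day: int = 1,
    hour: int = 9,
    urgency: str = "B",
    destination: str = "Hospital A",
    specialty: str = "General",
    patient_id: str | None = "p1",
    age: int | None = 75,
    seq: int = 0,
    year: int = 2015,
):
    return ef.RideRecord(
        timestamp=datetime(year, 1, 1) + timedelta(days=day - 1, hours=hour),
        urgency=urgency,
        destination=destination,
        specialty=specialty,
        patient_id=patient_id,
        age=age,
        seq=seq,
    )


def make_trace(labels, patient_id="p1", year=2015, **kwargs):
    """A trace visiting the given destination labels on consecutive days."""
    events = tuple(
        make_record(
            day=i + 1,
            destination=label,
            patient_id=patient_id,
            seq=i,
            year=year,
            **kwargs,
        )
        for i, label in enumerate(labels)
    )
    return ef.PatientTrace(patient_id=patient_id, events=events)


@pytest.fixture(scope="session")
def patient_b_traces():
    cleaned, _ = ef.clean_log(datasets.patient_b_log())
    return ef.build_traces(cleaned)


@pytest.fixture(scope="session")
def patient_a_trace():
    cleaned, _ = ef.clean_log(datasets.patient_a_excerpt_log())
    return ef.build_traces(cleaned)[0]


@pytest.fixture(scope="session")
def sim_small():
    """A small two-year synthetic cohort with corruption, plus its truth."""
    config = ef.SimulationConfig(
        seed=2024,
        years=(2014, 2015),
        n_patients_per_archetype={
            "drh_shuttle": 5,
            "chaotic_frail": 15,
            "episodic": 40,
            "one_off": 60,
        },
        missing_destination_rate=0.02,
        orphan_record_rate=0.01,
    )
    log, truth = ef.generate_log(config)
    return config, log, truth
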