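"""Reading, cleaning, trace building and serialization round trips."""

from __future__ import annotations

import io
from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emsflow as ef
from emsflow.event_log import ContractError, SchemaError

HEADER = "patient_id,date,time,urgency,destination,specialty,age\n"


def read_csv_text(text: str, **kwargs) -> ef.EventLog:
    return ef.read_rides(io.StringIO(text), **kwargs)


class TestReadRides:
    def test_empty_file_yields_empty_log(self):
        log = read_csv_text(HEADER)
        assert len(log) == 0
        assert log.provenance.rows_read == 0

    def test_dialysis_destination_row_parses_verbatim(self):
        log = read_csv_text(
            HEADER + "p1,2012-01-20,09:30:56,B,RegHospital 1-dialysis,Other specialties,81\n"
        )
        (record,) = log.records
        assert record.urgency == "B"
        assert record.destination == "RegHospital 1-dialysis"
        assert record.timestamp == datetime(2012, 1, 20, 9, 30, 56)
        assert record.age == 81

    def test_malformed_date_rejected_and_counted(self):
        text = HEADER + (
            "p1,2015-01-01,10:00:00,B,Hospital A,General,70\n"
            "p2,not-a-date,10:00:00,B,Hospital A,General,70\n"
            "p3,2015-02-30,10:00:00,B,Hospital A,General,70\n"
        )
        log = read_csv_text(text)
        assert len(log) == 1
        assert log.provenance.rows_rejected_bad_timestamp == 2
        assert log.provenance.rows_read == 3

    def test_missing_mandatory_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            read_csv_text("patient_id,date,time,specialty\np1,2015-01-01,10:00:00,General\n")

    def test_anonymize_hashes_ids_consistently(self):
        text = HEADER + (
            "alice,2015-01-01,10:00:00,B,Hospital A,General,70\n"
            "alice,2015-01-02,10:00:00,B,Hospital A,General,70\n"
        )
        log = read_csv_text(text, anonymize=True)
        ids = {r.patient_id for r in log.records}
        assert len(ids) == 1
        assert "alice" not in ids

    def test_alias_table_collapses_service_tag(self):
        schema = ef.SchemaConfig(aliases={"RegHospital 1-dialysis": "RegHospital 1"})
        log = read_csv_text(
            HEADER + "p1,2012-01-20,09:30:56,B,RegHospital 1-dialysis,Other specialties,\n",
            schema=schema,
        )
        assert log.records[0].destination == "RegHospital 1"

    def test_invalid_urgency_code_raises(self):
        with pytest.raises(ValueError, match="urgency"):
            read_csv_text(HEADER + "p1,2015-01-01,10:00:00,C,Hospital A,General,70\n")


class TestCleanLog:
    def test_single_orphan_record_dropped(self):
        log = read_csv_text(HEADER + ",2015-01-01,10:00:00,B,Hospital A,General,\n")
        cleaned, report = ef.clean_log(log)
        assert len(cleaned) == 0
        assert report.rows_dropped_no_patient == 1

    def test_empty_destination_marked_unknown(self):
        log = read_csv_text(HEADER + "p1,2015-01-01,10:00:00,B,,General,\n")
        cleaned, report = ef.clean_log(log)
        assert cleaned.records[0].destination == "Unknown"
        assert report.destinations_marked_unknown == 1

    def test_mixed_toy_log_counts(self):
        text = HEADER + (
            "p1,2015-01-01,10:00:00,B,Hospital A,General,70\n"
            ",2015-01-02,10:00:00,B,Hospital A,General,\n"
            ",2015-01-03,10:00:00,B,Hospital A,General,\n"
            "p2,2015-01-04,10:00:00,B,,General,66\n"
            "p3,2015-01-05,10:00:00,A1,Hospital D,Surgery,80\n"
        )
        cleaned, report = ef.clean_log(read_csv_text(text))
        assert len(cleaned) == 3
        assert (report.rows_dropped_no_patient, report.destinations_marked_unknown) == (2, 1)
        assert report.rows_read == 5

    def test_cleaning_is_idempotent_and_conserves_rows(self):
        text = HEADER + (
            "p1,2015-01-01,10:00:00,B,Hospital A,General,70\n"
            ",2015-01-02,10:00:00,B,,General,\n"
            "p2,bad-date,10:00:00,B,Hospital A,General,\n"
        )
        log = read_csv_text(text)
        once, report1 = ef.clean_log(log)
        twice, report2 = ef.clean_log(once)
        assert once.records == twice.records
        assert report1 == report2
        assert report1.rows_read == (
            report1.rows_retained
            + report1.rows_dropped_no_patient
            + report1.rows_rejected_bad_timestamp
        )


class TestBuildTraces:
    def test_singleton_trace_spans_one_day(self):
        log = read_csv_text(HEADER + "p1,2015-03-01,10:00:00,B,Hospital A,General,70\n")
        (trace,) = ef.build_traces(log)
        assert len(trace) == 1
        assert trace.span[0] == trace.span[1]

    def test_uncleaned_log_is_contract_violation(self):
        log = read_csv_text(HEADER + ",2015-03-01,10:00:00,B,Hospital A,General,\n")
        with pytest.raises(ContractError):
            ef.build_traces(log)

    def test_worked_example_sorts_chronologically(self, patient_b_traces):
        (trace,) = patient_b_traces
        assert len(trace) == 41
        assert trace.events[0].timestamp == datetime(2013, 6, 2, 2, 42, 14)
        assert trace.events[0].destination == "Hospital A"
        assert trace.events[-1].timestamp == datetime(2016, 1, 14, 8, 58, 3)
        assert trace.events[-1].destination == "Hospital D"

    def test_same_day_rides_ordered_by_time(self, patient_b_traces):
        (trace,) = patient_b_traces
        times = [e.timestamp for e in trace.events]
        assert times == sorted(times)
        # the two 2014-12-08 rides keep their printed time order
        same_day = [e for e in trace.events if e.timestamp.date().isoformat() == "2014-12-08"]
        assert [e.timestamp.hour for e in same_day] == [12, 16]

    def test_traces_partition_the_log(self, sim_small):
        _, log, _ = sim_small
        traces = ef.build_traces(log)
        assert sum(len(t) for t in traces) == len(log)
        seen = [e.seq for t in traces for e in t.events]
        assert len(seen) == len(set(seen))

    def test_tied_timestamps_keep_input_order(self):
        text = HEADER + (
            "p1,2015-01-01,10:00:00,B,First,General,70\n"
            "p1,2015-01-01,10:00:00,B,Second,General,70\n"
        )
        (trace,) = ef.build_traces(read_csv_text(text))
        assert [e.destination for e in trace.events] == ["First", "Second"]


class TestSerialization:
    def test_empty_log_round_trips(self, tmp_path):
        log = read_csv_text(HEADER)
        path = tmp_path / "empty.csv"
        ef.write_log(log, path)
        assert len(ef.read_rides(path)) == 0

    def test_delimited_round_trip_field_for_field(self, tmp_path, sim_small):
        _, log, _ = sim_small
        subset = ef.EventLog(records=log.records[:50], provenance=log.provenance)
        path = tmp_path / "rides.csv"
        ef.write_log(subset, path)
        back = ef.read_rides(path)
        assert back.records == subset.records

    def test_xes_round_trip_of_worked_example(self, tmp_path, patient_b_traces):
        path = tmp_path / "log.xes"
        ef.write_log(patient_b_traces, path, format="xes")
        back = ef.read_xes(path)
        assert len(back) == 1
        assert len(back[0]) == 41
        assert back[0].activities() == patient_b_traces[0].activities()

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["p1", "p2", "p3"]),
                st.integers(1, 28),
                st.sampled_from(["A1", "A2", "B"]),
                st.sampled_from(["Hospital A", "Nursing home", "EMS-S&T", "RegHospital 1"]),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_random_logs_round_trip(self, tmp_path_factory, rows):
        from conftest import make_record

        records = [
            make_record(day=day, urgency=urg, destination=dest, patient_id=pid, seq=i)
            for i, (pid, day, urg, dest) in enumerate(rows)
        ]
        log = ef.EventLog(records=records)
        path = tmp_path_factory.mktemp("rt") / "log.csv"
        ef.write_log(log, path)
        assert ef.read_rides(path).records == records
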