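"""Cohort identification, the rounding rule, and the annual summary tables."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emsflow as ef
from emsflow import datasets
from emsflow.cohorts import round_half_up

from conftest import make_record, make_trace


class TestRoundingAndRates:
    # every published (part, whole, percent) cell of the regional overview
    @pytest.mark.parametrize(
        "part, whole, expected",
        [
            (5051, 31300, 16),
            (4636, 32359, 14),
            (5681, 34568, 16),
            (5976, 36742, 16),
            (6449, 38763, 17),
            (6258, 39235, 16),
            (2607, 5051, 52),
            (2428, 4636, 52),
            (2792, 5681, 49),
            (3169, 5976, 53),
            (3333, 6449, 52),
            (3615, 6258, 58),
            (302, 395, 76),
            (345, 395, 87),
            (75, 395, 19),
            (326, 395, 83),  # 82.53 -> 83 pins half-away-from-zero rounding
            (0, 50, 0),
        ],
    )
    def test_share_pct_reproduces_published_cells(self, part, whole, expected):
        assert ef.share_pct(part, whole) == expected

    @pytest.mark.parametrize(
        "earlier, later, expected",
        [(395, 628, 59), (100, 100, 0), (728, 502, -31)]
        + [(e, l, p) for e, l, p in datasets.PUBLISHED_TREND_FIGURES.values()],
    )
    def test_percent_change_reproduces_published_trends(self, earlier, later, expected):
        assert ef.percent_change(earlier, later) == expected

    def test_degenerate_denominators_raise(self):
        with pytest.raises(ValueError):
            ef.share_pct(1, 0)
        with pytest.raises(ValueError):
            ef.percent_change(0, 10)

    def test_round_half_up_ties_away_from_zero(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(-2.5) == -3

    def test_published_column_totals_equal_annual_sums(self):
        regional = datasets.regional_utilization_counts()
        frail = datasets.frail_needs_urgency_counts()
        totals = datasets.PUBLISHED_TOTALS
        for column in regional.columns.drop("year"):
            assert regional[column].sum() == totals[column]
        for column in frail.columns.drop("year"):
            key = column.replace("frail_patients_total", "frail_elderly").replace(
                "frail_calls_total", "frail_calls"
            )
            assert frail[column].sum() == totals[key]


class TestClassifyDrh:
    def test_planned_dialysis_destination_is_drh(self):
        record = make_record(urgency="B", destination="RegHospital 1-dialysis")
        assert ef.classify_drh(record)

    def test_planned_ride_without_keyword_is_not(self):
        record = make_record(
            urgency="B", destination="Nursing home", specialty="Internal medicine"
        )
        assert not ef.classify_drh(record)

    def test_urgent_ride_is_never_drh(self):
        record = make_record(urgency="A1", destination="RegHospital 1-dialysis")
        assert not ef.classify_drh(record)

    def test_keyword_found_in_specialty_field(self):
        record = make_record(urgency="B", destination="Hospital A", specialty="Radiation therapy")
        assert ef.classify_drh(record)


class TestYearlyMemberships:
    def test_below_threshold_is_not_frequent(self):
        trace = make_trace(["Hospital A"] * 3)
        row = ef.yearly_memberships([trace]).iloc[0]
        assert row["calls_in_year"] == 3 and not row["is_frequent"]

    def test_worked_example_is_frequent_in_2015(self, patient_b_traces):
        memberships = ef.yearly_memberships(patient_b_traces)
        row = memberships.set_index("year").loc[2015]
        assert row["calls_in_year"] == 27
        assert bool(row["is_frequent"])

    def test_unknown_destinations_count_toward_calls(self):
        trace = make_trace(["Unknown", "Unknown", "Hospital A", "Unknown"])
        row = ef.yearly_memberships([trace]).iloc[0]
        assert row["calls_in_year"] == 4 and row["is_frequent"]

    def test_frailty_requires_age_and_frequency(self):
        young = make_trace(["Hospital A"] * 5, patient_id="young", age=40)
        old_rare = make_trace(["Hospital A"] * 2, patient_id="old_rare", age=80)
        old_freq = make_trace(["Hospital A"] * 5, patient_id="old_freq", age=80)
        memberships = ef.yearly_memberships([young, old_rare, old_freq])
        frail = set(memberships.loc[memberships["is_frail_elderly"], "patient_id"])
        assert frail == {"old_freq"}

    def test_planted_frequent_users_recovered_exactly(self, sim_small):
        _, log, truth = sim_small
        memberships = ef.yearly_memberships(ef.build_traces(log))
        found = {
            (row.patient_id, row.year)
            for row in memberships.itertuples()
            if row.is_frequent
        }
        planted = {
            (pid, year) for year, pids in truth.frequent_by_year.items() for pid in pids
        }
        assert found == planted

    def test_planted_drh_memberships_recovered_exactly(self, sim_small):
        _, log, truth = sim_small
        memberships = ef.yearly_memberships(ef.build_traces(log))
        found = {
            (row.patient_id, row.year)
            for row in memberships.itertuples()
            if row.is_B_DRH
        }
        planted = {(pid, year) for year, pids in truth.drh_by_year.items() for pid in pids}
        assert found == planted

    @settings(max_examples=30, deadline=None)
    @given(
        counts=st.lists(st.integers(1, 12), min_size=1, max_size=8),
        low=st.integers(1, 6),
        bump=st.integers(1, 5),
    )
    def test_raising_threshold_shrinks_frequent_set(self, counts, low, bump):
        traces = [
            make_trace(["Hospital A"] * n, patient_id=f"p{i}")
            for i, n in enumerate(counts)
        ]
        loose = ef.yearly_memberships(traces, ef.CohortParams(frequent_threshold=low))
        strict = ef.yearly_memberships(
            traces, ef.CohortParams(frequent_threshold=low + bump)
        )
        loose_set = set(loose.loc[loose["is_frequent"], "patient_id"])
        strict_set = set(strict.loc[strict["is_frequent"], "patient_id"])
        assert strict_set <= loose_set


class TestSummaries:
    def test_annual_summary_matches_ground_truth_counts(self, sim_small):
        _, log, truth = sim_small
        memberships = ef.yearly_memberships(ef.build_traces(log))
        annual = ef.summarize_annual(memberships)
        per_year = annual.per_year.set_index("year")
        for year, expected in truth.records_per_year.items():
            assert per_year.loc[year, "all_calls"] == expected
            assert per_year.loc[year, "frequent_users"] == len(
                truth.frequent_by_year[year]
            )

    def test_totals_row_sums_and_unique_counts(self):
        # one patient frequent in both years: annual counts sum to 2,
        # distinct count is 1
        traces = [
            make_trace(["Hospital A"] * 5, patient_id="p1", year=2014),
            make_trace(["Hospital A"] * 6, patient_id="p1", year=2015),
            make_trace(["Hospital A"] * 2, patient_id="p2", year=2015),
        ]
        # merge the two p1 traces into one multi-year trace
        events = tuple(
            sorted(
                traces[0].events + traces[1].events, key=lambda e: e.timestamp
            )
        )
        merged = [ef.PatientTrace(patient_id="p1", events=events), traces[2]]
        annual = ef.summarize_annual(ef.yearly_memberships(merged))
        assert annual.totals["frequent_users"] == 2
        assert annual.totals["frequent_users_unique"] == 1
        assert annual.totals["all_patients"] == 3
        assert annual.totals["all_patients_unique"] == 2

    def test_empty_year_gives_zero_row_with_absent_percentages(self):
        traces = [make_trace(["Hospital A"] * 5, year=2014)]
        params = ef.CohortParams(year_range=(2014, 2015))
        annual = ef.summarize_annual(ef.yearly_memberships(traces, params), params)
        row = annual.per_year.set_index("year").loc[2015]
        assert row["all_calls"] == 0
        assert row["all_patients"] == 0
        assert pd.isna(row["frequent_calls_pct_of_all"])

    def test_needs_urgency_call_columns_are_additive(self, sim_small):
        _, log, truth = sim_small
        memberships = ef.yearly_memberships(ef.build_traces(log))
        needs = ef.summarize_needs_urgency(memberships)
        for row in needs.per_year.itertuples():
            assert row.frail_calls_A + row.frail_calls_B == row.frail_calls_total
            assert row.frail_calls_B_DRH + row.frail_calls_B_other == row.frail_calls_B

    def test_comorbid_patient_counted_in_both_b_columns(self):
        events = (
            make_record(day=1, urgency="B", destination="RegHospital 1-dialysis", seq=0),
            make_record(day=2, urgency="B", destination="Hospital A", seq=1),
            make_record(day=3, urgency="B", destination="Hospital A", seq=2),
            make_record(day=4, urgency="B", destination="RegHospital 1-dialysis", seq=3),
        )
        trace = ef.PatientTrace(patient_id="p1", events=events)
        needs = ef.summarize_needs_urgency(ef.yearly_memberships([trace]))
        row = needs.per_year.iloc[0]
        assert row["frail_patients_B_DRH"] == 1
        assert row["frail_patients_B_other"] == 1
        assert row["frail_patients_total"] == 1

    def test_a_only_patient_not_in_b_columns(self):
        trace = make_trace(["Hospital A"] * 4, urgency="A1")
        needs = ef.summarize_needs_urgency(ef.yearly_memberships([trace]))
        row = needs.per_year.iloc[0]
        assert row["frail_patients_A"] == 1
        assert row["frail_patients_B"] == 0
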