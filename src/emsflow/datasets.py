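"""Built-in reference data: two worked-example routings and published
annual utilization figures from a six-year (2012–2017) study of EMS ride
records in a Dutch province.

Three small datasets ship with the package:

* :func:`patient_a_excerpt_log` — six rides of a low-complexity dialysis
  "shuttle" patient alternating between a nursing home and one regional
  hospital.
* :func:`patient_b_log` — the complete 41-ride routing of a high-complexity
  frequent user, printed out of chronological order at the source exactly as
  extracted (IDs 1–41), which makes it a natural fixture for the sorting and
  mining pipeline.
* :func:`regional_utilization_counts` / :func:`frail_needs_urgency_counts` —
  the published per-year patient and call counts for the whole region, the
  frequent-user subset and the frail-elderly subset, from which every
  published percentage and trend figure can be recomputed.

The published totals are kept alongside in :data:`PUBLISHED_TOTALS` for
cross-checking column sums.
"""

from __future__ import annotations

import io

import pandas as pd

from .event_log import EventLog, read_rides

__all__ = [
    "patient_a_excerpt_log",
    "patient_b_log",
    "regional_utilization_counts",
    "frail_needs_urgency_counts",
    "PUBLISHED_TOTALS",
    "PUBLISHED_TREND_FIGURES",
]

_PATIENT_A_CSV = """\
patient_id,date,time,urgency,destination,specialty,age
patient-A,2012-01-06,16:06:15,B,Nursing home,Other specialties,
patient-A,2012-01-19,15:46:06,B,Nursing home,Internal medicine,
patient-A,2012-01-20,09:30:56,B,RegHospital 1-dialysis,Other specialties,
patient-A,2012-01-23,10:15:32,B,RegHospital 1-dialysis,Other specialties,
patient-A,2012-01-23,15:16:49,B,Nursing home,Internal medicine,
patient-A,2012-01-25,09:11:57,B,RegHospital 1-dialysis,Other specialties,
"""

# The 41 rides of patient B in original extraction order (not chronological).
_PATIENT_B_CSV = """\
patient_id,date,time,urgency,destination,specialty,age
patient-B,2013-09-13,06:50:39,A1,EMS-S&T,Other specialties,
patient-B,2013-06-02,02:42:14,A1,Hospital A,Other specialties,
patient-B,2013-06-16,13:50:06,A2,Hospital A,Other specialties,
patient-B,2013-07-02,00:04:43,A1,Hospital A,Pulmonology,
patient-B,2014-02-01,20:40:56,A2,Hospital A,Other specialties,
patient-B,2014-02-01,23:09:41,A2,Unknown,Other specialties,
patient-B,2014-11-26,22:26:42,A1,Hospital A,Other specialties,
patient-B,2014-12-06,11:22:00,A1,Hospital A,Pulmonology,
patient-B,2014-12-08,12:51:39,A1,Hospital A,Surgery,
patient-B,2014-12-08,16:14:38,B,Unknown,Other specialties,
patient-B,2014-02-17,11:42:49,A1,Hospital A,Pulmonology,
patient-B,2014-04-02,09:37:52,B,RegHospital 2,Other specialties,
patient-B,2015-09-05,08:43:23,A1,RegHospital 4,General,
patient-B,2015-09-05,11:04:53,B,Unknown,Unknown,
patient-B,2015-09-23,01:51:15,A2,Hospital D,General,
patient-B,2015-10-22,07:57:29,A2,Hospital D,General,
patient-B,2015-02-06,09:56:39,A2,Hospital A,Pulmonology,
patient-B,2015-02-06,11:56:25,A2,Nursing home,Pulmonology,
patient-B,2015-02-12,11:05:34,A1,Hospital A,Pulmonology,
patient-B,2015-02-12,12:47:12,B,Nursing home,Pulmonology,
patient-B,2015-02-26,08:57:59,B,Hospital A,Other specialties,
patient-B,2015-02-26,10:47:32,B,Nursing home,Other specialties,
patient-B,2015-01-07,08:16:58,A1,Hospital A,Other specialties,
patient-B,2015-01-07,10:02:35,A1,Unknown,Other specialties,
patient-B,2015-01-07,11:48:10,A1,RegHospital 1,Surgery,
patient-B,2015-03-15,05:22:40,A1,EMS-S&T,Other specialties,
patient-B,2015-01-11,16:09:12,A2,Hospital A,Other specialties,
patient-B,2015-01-11,17:46:08,B,RegHospital 1,Other specialties,
patient-B,2015-04-30,14:39:22,A2,Hospital A,Pulmonology,
patient-B,2015-04-30,16:02:48,B,Unknown,Pulmonology,
patient-B,2015-01-14,08:55:44,B,Hospital A,Pulmonology,
patient-B,2015-06-23,16:47:33,A2,Hospital A,Pulmonology,
patient-B,2015-06-23,19:00:12,B,Unknown,Pulmonology,
patient-B,2015-06-28,10:43:34,A1,Hospital A,General,
patient-B,2015-06-28,21:01:32,A1,RegHospital 1,Pulmonology,
patient-B,2015-07-10,11:45:13,A1,Hospital D,General,
patient-B,2015-07-12,12:09:24,A1,RegHospital 1,Internal medicine,
patient-B,2015-07-12,14:21:53,B,Unknown,Internal medicine,
patient-B,2015-01-21,21:39:06,A2,Hospital A,Pulmonology,
patient-B,2016-01-14,08:58:03,A2,Hospital D,Pulmonology,
patient-B,2016-01-02,22:08:36,A1,Hospital D,Pulmonology,
"""

# Published regional overview, one row per year: counts of all patients and
# calls, the frequent-user subset, and the frail-elderly subset of frequent
# users (patient counts and their calls).
_REGIONAL_ROWS = [
    # year, all_patients, all_calls, frequent_users, frequent_calls,
    # frail_elderly, frail_calls
    (2012, 22551, 31300, 731, 5051, 395, 2607),
    (2013, 23794, 32359, 625, 4636, 320, 2428),
    (2014, 24355, 34568, 844, 5681, 446, 2792),
    (2015, 25677, 36742, 987, 5976, 548, 3169),
    (2016, 27146, 38763, 999, 6449, 561, 3333),
    (2017, 27671, 39235, 1043, 6258, 628, 3615),
]

# Published needs-and-urgency breakdown for frail elderly users: per year,
# patients with >=1 ride of each category (categories overlap) and the call
# counts per category (A + B = total; B-DRH + B-other = B).
_FRAIL_ROWS = [
    # year, patients_total, patients_A, patients_B, patients_B_DRH,
    # patients_B_other, calls_total, calls_A, calls_B, calls_B_DRH,
    # calls_B_other
    (2012, 395, 302, 345, 75, 326, 2607, 825, 1782, 728, 1054),
    (2013, 320, 258, 271, 64, 256, 2428, 664, 1764, 903, 861),
    (2014, 446, 372, 370, 74, 353, 2792, 1019, 1773, 740, 1033),
    (2015, 548, 473, 408, 83, 395, 3169, 1478, 1691, 533, 1158),
    (2016, 561, 498, 417, 99, 398, 3333, 1552, 1781, 575, 1206),
    (2017, 628, 561, 501, 104, 487, 3615, 1729, 1886, 502, 1384),
]

#: Published column totals. ``*_unique`` entries count distinct patients over
#: the whole period (less than the sum of annual counts because patients
#: recur across years).
PUBLISHED_TOTALS = {
    "all_patients": 151_194,
    "all_patients_unique": 126_758,
    "all_calls": 212_967,
    "frequent_users": 5229,
    "frequent_users_unique": 4734,
    "frequent_calls": 34_051,
    "frail_elderly": 2898,
    "frail_elderly_unique": 2700,
    "frail_calls": 17_944,
    "frail_patients_A": 2464,
    "frail_patients_A_unique": 2303,
    "frail_patients_B": 2312,
    "frail_patients_B_unique": 842,
    "frail_patients_B_DRH": 499,
    "frail_patients_B_DRH_unique": 480,
    "frail_patients_B_other": 2215,
    "frail_patients_B_other_unique": 2119,
    "frail_calls_A": 7267,
    "frail_calls_B": 10_677,
    "frail_calls_B_DRH": 3981,
    "frail_calls_B_other": 6696,
    "records_not_linked_to_patients": 2494,
}

#: Published narrative trend statistics as (earlier, later, printed percent).
PUBLISHED_TREND_FIGURES = {
    "all_calls_2012_2017": (31_300, 39_235, 25),
    "frail_users_2012_2017": (395, 628, 59),
    "frail_calls_2012_2017": (2607, 3615, 39),
    "frail_users_2013_2015": (320, 548, 71),
    "frail_calls_A_2012_2017": (825, 1729, 110),
    "frail_calls_B_2012_2017": (1782, 1886, 6),
    "frail_calls_A_2013_2015": (664, 1478, 123),
    "drh_users_2012_2017": (75, 104, 39),
    "b_other_users_2012_2017": (326, 487, 49),
    "drh_calls_2012_2017": (728, 502, -31),
    "b_other_calls_2012_2017": (1054, 1384, 31),
}


def patient_a_excerpt_log() -> EventLog:
    """Six-ride excerpt of the dialysis-shuttle exemplar (patient A)."""
    return read_rides(io.StringIO(_PATIENT_A_CSV))


def patient_b_log() -> EventLog:
    """The complete 41-ride routing of the high-complexity exemplar."""
    return read_rides(io.StringIO(_PATIENT_B_CSV))


def regional_utilization_counts() -> pd.DataFrame:
    """Published annual overview counts (see module docstring)."""
    return pd.DataFrame(
        _REGIONAL_ROWS,
        columns=[
            "year",
            "all_patients",
            "all_calls",
            "frequent_users",
            "frequent_calls",
            "frail_elderly",
            "frail_calls",
        ],
    )


def frail_needs_urgency_counts() -> pd.DataFrame:
    """Published frail-elderly needs-and-urgency counts (see module docstring)."""
    return pd.DataFrame(
        _FRAIL_ROWS,
        columns=[
            "year",
            "frail_patients_total",
            "frail_patients_A",
            "frail_patients_B",
            "frail_patients_B_DRH",
            "frail_patients_B_other",
            "frail_calls_total",
            "frail_calls_A",
            "frail_calls_B",
            "frail_calls_B_DRH",
            "frail_calls_B_other",
        ],
    )
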