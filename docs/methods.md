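# Methods

## Data model and cleaning

The unit of observation is one ambulance ride: timestamp (second
resolution), urgency code (A1/A2 urgent, B planned), destination label,
requested specialty, patient id, and patient age in years. Cleaning is total
and idempotent: rows whose timestamp does not parse to a real calendar
instant are rejected at read time; rows without a patient id are dropped
(they cannot belong to any routing); empty destination or specialty labels
become the literal `Unknown`. Every count is conserved —
`rows_read = retained + dropped + rejected` holds for every input — and the
cleaning report carries the cumulative counts, so cleaning twice changes
nothing.

Destination labels are taken verbatim; no fuzzy merging is attempted. An
optional alias table in the schema config can collapse service-tagged labels
(`RegHospital 1-dialysis` → `RegHospital 1`) when the coarser provider
granularity is wanted. Timestamp ties within a patient keep stable input
order (a sequence index recorded at read time); source systems rarely
guarantee sub-second ordering, and no downstream statistic depends on the
choice beyond determinism. Patient-id hashing is available at read time for
logs that arrive unanonymized.

## Cohort definitions

* **Frequent user**: ≥ `frequent_threshold` rides (default 4) within one
  *calendar* year. A calendar year, not a rolling window, because the
  reporting unit of the utilization tables is the year. All rides count,
  including rides to `Unknown` destinations — the criterion is a ride count.
* **Frail elderly**: frequent users aged ≥ `frail_age_min` (default 70).
  Frailty is nested inside frequent-user status for the same year. Age is
  evaluated at the patient's first ride of the year (configurable to the
  per-year maximum); the simulator uses age-at-ride semantics.
* **B-DRH**: a planned (B) ride whose destination *or* specialty contains a
  DRH keyword (`dialysis`, `radiation`, `hyperbaric`; case-insensitive
  substring, configurable), because source systems encode the need in either
  field. Urgent rides are never DRH by definition — DRH identifies planned,
  predictable transport. A patient can be both B-DRH and B-other in the same
  year (comorbidity), so patient columns in the needs/urgency table may sum
  to more than the annual total, while call columns are additive
  (A + B = total, B-DRH + B-other = B).

All percentages and percent changes use one rounding rule: half away from
zero to the nearest integer. The rule is pinned by the published cell
326/395 → 83 (82.53 would round to 82 under half-even or truncation).

## Process maps

The directly-follows graph is mined per trace collection: node weight =
number of rides to that activity, arc weight = number of immediate
successions within one patient's routing, plus start/end counts per trace.
Conservation laws (Σ nodes = events, Σ arcs = events − cases,
Σ starts = Σ ends = cases) are validated after mining and checked against a
brute-force pair-enumeration oracle in the tests. Directly-follows pairs
never cross patients and have no maximum time gap by default (multi-year
maps are the norm); per-year maps are built by restricting each trace to the
calendar year *before* mining, so a case is the patient's within-year
sequence.

Self-loops are first-class: consecutive identical destinations are mined as
an arc from the activity to itself and interpreted as transport legs
organized outside the EMS operator, not as data errors. `Unknown` and
`EMS-S&T` are first-class activities (on-scene treatment is a formal care
provider here), removable via an exclusion list; a trace emptied by the
exclusion stops counting as a case.

Filtering (defaults 30 events/node, 8 per arc — the thresholds used for
rendering busy multi-provider maps) produces a *view*: surviving
frequencies are untouched, arcs are dropped when below threshold or when an
endpoint is dropped, and the original totals are retained in provenance.
Filtering is monotone and idempotent. Map diffs partition the arc union into
added (rendered red on the later map), removed (rendered green on the
earlier map) and shared-with-delta. DOT export is deterministic (sorted node
and edge emission), so identical maps export byte-identically.

## Complexity classification

Per patient: event count, distinct providers and specialties (excluding
`Unknown` by default — a missing label is a data artifact, not a provider),
distinct arcs of the patient's own map, Shannon entropy (bits) of the
provider-visit distribution, and the fraction of rides that are B-DRH. The
low/high dichotomy has no canonical numeric criterion; the default rule —
low iff `n_distinct_providers ≤ 2` **and** `drh_share > 0` — is
operationalized from the two exemplar routings (a dialysis shuttle between
one hospital and a nursing home vs. a 7-provider mixed-urgency routing) and
is fully configurable (`max_providers_low`, `require_drh_for_low`). The
classification depends only on the label multiset, so it is invariant to
event order.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the confidential source marginals. Four archetypes:

| archetype | call process | urgency | providers | ages (min/mode/max) |
|---|---|---|---|---|
| `drh_shuttle` | periodic, ~3 d ± 1 d; paired return ride, 15 % missing legs | all B | 1 dialysis hospital + nursing home | 70/78/92 |
| `chaotic_frail` | Poisson(8)/yr, floor 4 | 30/25/45 % A1/A2/B | 6 distinct | 70/82/95 |
| `episodic` | Poisson(2.5)/yr | mixed | 3 | 40/65/85 |
| `one_off` | 1 ride | mostly urgent | 1 | 18/55/95 |

The missing-leg probability is what produces the shuttle's characteristic
self-loops; for any binary shuttle sequence the two cross-arc frequencies
differ by at most one, a property the tests assert. `chaotic_frail` is
constructed with at least 4 rides over at least 3 distinct providers so that
the planted complexity label is exactly recoverable under the default rule —
a deliberate construction, documented rather than hidden, because recovery
tests need planted labels the rule can in principle recover.

Recruitment is per calendar year and grows at the background EMS transport
growth rate (default 5.1 %/year); `chaotic_frail` recruitment is multiplied
by a policy-shock factor (default 2.0) from the shock year (default 2014)
onward, emulating the surge in high-complexity frail elderly users after
long-term-care reform shifted care into the home setting. Patients generate
rides within their recruitment year only — a simplification that keeps the
yearly ground-truth flags trivially consistent; multi-year routings are
covered by the bundled worked examples instead. Within-day times are
uniform and there is no weekday structure: the analysis uses time only for
ordering. All sampling flows through a single `numpy` generator seeded from
the config, so a config + seed pair reproduces the log byte for byte.
Corruption (orphaned rows, blanked destinations) injects *exactly*
`round(rate · n)` rows each, drawn without replacement and disjointly, so
injected counts can be compared one-to-one with the cleaning report.

What passing on synthetic data shows — and does not show: the pipeline's
counting, mining and classification are exact and deterministic on logs with
the assumed schema; it does not validate distributional realism (no seasonal
structure, no inter-provider referral preferences, no age drift within a
year, no duplicate patient identities).

## Problem sizes and numerical choices

The test suite and the acceptance script run on a two-year cohort of roughly
1000 patients (~14 000 rides) plus the 41-ride worked example; these sizes
were chosen as the smallest at which every recovery statement is about a
population rather than a handful of patients, and they keep the full suite
in the tens of seconds. Rate arithmetic uses exact `Decimal` division of
integer counts before rounding, so rounding behaviour does not depend on
binary floating point. Degenerate inputs are explicit errors rather than
silent defaults: empty trace collections, zero denominators in rates,
uncleaned logs passed to trace building, and corruption rates outside
[0, 1] all raise.

## Known limitations

* Frailty is age-based only; no clinical frailty score is computed.
* Destination labels are not normalized across spelling variants unless an
  alias table is supplied.
* The low/high complexity rule is a falsifiable operationalization of a
  qualitative dichotomy, not a validated clinical instrument.
* XES export covers the attributes this pipeline uses (activity, timestamp,
  urgency, specialty, age), not the full XES extension ecosystem.
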