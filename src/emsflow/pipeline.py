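"""End-to-end orchestration: read → clean → traces → cohorts → maps → complexity.

The pipeline is a fixed sequence of the library stages, writing every
intermediate artifact plus a manifest (parameter set, input checksums,
package version) so a run can be audited and reproduced. Rerunning with
identical inputs and config produces byte-identical artifacts except for the
timestamps in the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohorts import (
    CohortParams,
    classify_drh,
    summarize_annual,
    summarize_needs_urgency,
    yearly_memberships,
)
from .complexity import (
    ComplexityRule,
    classify_complexity,
    cohort_complexity_table,
    profile_patient,
)
from .event_log import (
    SchemaConfig,
    build_traces,
    clean_log,
    read_rides,
    traces_for_year,
    write_log,
)
from .process_map import MapFilterSpec, diff_maps, export_dot, filter_map, mine_dfg

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("emsflow")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    input_path: Path
    out_dir: Path
    schema: SchemaConfig = field(default_factory=SchemaConfig)
    cohort_params: CohortParams = field(default_factory=CohortParams)
    filter_spec: MapFilterSpec = field(default_factory=lambda: MapFilterSpec(30, 8))
    complexity_rule: ComplexityRule = field(default_factory=ComplexityRule)
    activity_field: str = "destination"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides take precedence over the file."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cohort_raw = raw.get("cohorts", {})
        if "drh_keywords" in cohort_raw:
            cohort_raw["drh_keywords"] = frozenset(cohort_raw["drh_keywords"])
        if "year_range" in cohort_raw and cohort_raw["year_range"] is not None:
            cohort_raw["year_range"] = tuple(cohort_raw["year_range"])
        return cls(
            input_path=Path(raw["input_path"]),
            out_dir=Path(raw["out_dir"]),
            cohort_params=CohortParams(**cohort_raw),
            filter_spec=MapFilterSpec(**raw.get("map_filter", {"min_node_freq": 30, "min_arc_freq": 8})),
            complexity_rule=ComplexityRule(**raw.get("complexity", {})),
            activity_field=raw.get("activity_field", "destination"),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return the artifact paths keyed by artifact name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log = _stage("read")(read_rides)(config.input_path, config.schema)
    logger.info("read %d rows from %s", log.provenance.rows_read, config.input_path)

    cleaned, report = _stage("clean")(clean_log)(log)
    artifacts["cleaned_log"] = out / "cleaned_rides.csv"
    write_log(cleaned, artifacts["cleaned_log"])
    artifacts["cleaning_report"] = out / "cleaning_report.json"
    artifacts["cleaning_report"].write_text(
        json.dumps(dataclasses.asdict(report), indent=2)
    )

    traces = _stage("traces")(build_traces)(cleaned)
    logger.info("built %d patient traces", len(traces))

    params = config.cohort_params
    memberships = _stage("cohorts")(yearly_memberships)(traces, params)
    artifacts["memberships"] = out / "memberships.csv"
    memberships.to_csv(artifacts["memberships"], index=False)

    annual = _stage("summaries")(summarize_annual)(memberships, params)
    needs = summarize_needs_urgency(memberships, params)
    artifacts["annual_summary"] = out / "annual_summary.csv"
    annual.per_year.to_csv(artifacts["annual_summary"], index=False)
    artifacts["needs_urgency"] = out / "needs_urgency.csv"
    needs.per_year.to_csv(artifacts["needs_urgency"], index=False)
    artifacts["summary_totals"] = out / "summary_totals.json"
    artifacts["summary_totals"].write_text(
        json.dumps(
            {
                "annual": {k: _jsonable(v) for k, v in annual.totals.items()},
                "needs_urgency": {k: _jsonable(v) for k, v in needs.totals.items()},
            },
            indent=2,
        )
    )

    years = params.years(memberships["year"].unique() if len(memberships) else [])
    maps = {}
    for year in years:
        year_traces = traces_for_year(traces, year)
        if not year_traces:
            continue
        pm = mine_dfg(year_traces, config.activity_field)
        maps[year] = pm
        filtered = filter_map(pm, config.filter_spec)
        artifacts[f"map_{year}_json"] = out / f"map_{year}.json"
        pm.to_json(artifacts[f"map_{year}_json"])
        artifacts[f"map_{year}_dot"] = out / f"map_{year}.dot"
        artifacts[f"map_{year}_dot"].write_text(export_dot(filtered))
    _stage("maps")(lambda: None)()

    if len(maps) >= 2:
        first, last = min(maps), max(maps)
        diff = diff_maps(maps[first], maps[last])
        artifacts["map_diff_dot"] = out / f"map_diff_{first}_{last}.dot"
        artifacts["map_diff_dot"].write_text(
            export_dot(filter_map(maps[last], config.filter_spec), diff)
        )
    _stage("diffs")(lambda: None)()

    drh = lambda record: classify_drh(record, params)  # noqa: E731
    profiles = [
        classify_complexity(profile_patient(t, drh), config.complexity_rule)
        for t in traces
    ]
    table = cohort_complexity_table(profiles)
    artifacts["complexity"] = out / "complexity.csv"
    table.to_csv(artifacts["complexity"], index=False)
    _stage("complexity")(lambda: None)()

    manifest = {
        "emsflow_version": __version__,
        "input": {"path": str(config.input_path), "sha256": _sha256(Path(config.input_path))},
        "parameters": {
            "cohorts": {
                **dataclasses.asdict(params),
                "drh_keywords": sorted(params.drh_keywords),
            },
            "map_filter": dataclasses.asdict(config.filter_spec),
            "complexity": dataclasses.asdict(config.complexity_rule),
            "activity_field": config.activity_field,
        },
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    artifacts["manifest"] = out / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2))
    return artifacts


def _jsonable(value):
    if pd.isna(value):
        return None
    return int(value)
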