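"""The full exposure-to-risk pipeline and its human-readable report.

Stage order: consumption loads -> WWTP removal -> sediment-water
partitioning -> risk quotients.  Each stage that lacks its inputs is marked
incomplete in the MANIFEST rather than failing the run; the report itself is
byte-deterministic for identical inputs and configuration (timestamps are
isolated to the MANIFEST).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .exposure import load_estimates, load_table
from .io import Registries, RunConfig, load_tables
from .partitioning import partition_results, partition_table
from .removal import pairs_from_measurements, removal_efficiency, removal_table
from .risk import risk_results, risk_table

log = logging.getLogger("pharmfate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineResult:
    config: RunConfig
    loads: pd.DataFrame | None = None
    removal: pd.DataFrame | None = None
    partition: pd.DataFrame | None = None
    risk: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def complete_stages(self) -> list[str]:
        return [
            name
            for name, frame in [
                ("loads", self.loads),
                ("removal", self.removal),
                ("partition", self.partition),
                ("risk", self.risk),
            ]
            if frame is not None
        ]


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages on the configured inputs and write the output
    bundle (four CSVs, report.md, MANIFEST.json) into ``outdir``."""
    log.info("defaults: wastewater %.0f L/capita/day, region population %d, "
             "censored_as_point=%s",
             config.wastewater_L_per_capita_day, config.region_population,
             config.censored_as_point)
    registries = load_tables(config)
    result = PipelineResult(config=config)

    # --- consumption loads -------------------------------------------------
    if registries.consumption:
        served = max(config.population_served.values(), default=None)
        estimates = load_estimates(
            registries.consumption,
            registries.compounds,
            population_served=served,
            region_population=config.region_population if served else None,
            wastewater_L_per_capita_day=config.wastewater_L_per_capita_day,
        )
        result.loads = load_table(registries.consumption, estimates)
    else:
        result.warnings.append("no consumption data: load stage skipped")

    # --- WWTP removal ------------------------------------------------------
    pairs = pairs_from_measurements(registries.measurements)
    if pairs:
        results = [removal_efficiency(p) for p in pairs]
        result.removal = removal_table(results)
    else:
        result.warnings.append("no influent/effluent pairs: removal stage skipped")

    # --- partitioning ------------------------------------------------------
    part = partition_results(
        registries.measurements, censored_as_point=config.censored_as_point
    )
    if part:
        result.partition = partition_table(part)
    else:
        result.warnings.append(
            "no co-located sediment/water pairs: partition stage skipped"
        )

    # --- risk --------------------------------------------------------------
    if registries.endpoints or registries.measurements:
        compounds = sorted(registries.compounds) if registries.compounds else None
        res = risk_results(
            registries.measurements,
            registries.endpoints,
            site=config.risk_site,
            compounds=compounds,
        )
        if not registries.endpoints:
            result.warnings.append(
                "no endpoints supplied: all compounds unassessable"
            )
        result.risk = risk_table(res)

    _write_bundle(result, Path(outdir))
    return result


def markdown_table(frame: pd.DataFrame, float_fmt: str = "{:g}") -> str:
    """Render a DataFrame as a GitHub-style Markdown table."""
    if isinstance(frame.columns, pd.MultiIndex):
        headers = [" / ".join(str(part) for part in col) for col in frame.columns]
        frame = frame.copy()
        frame.columns = headers
    if frame.index.name:
        frame = frame.reset_index()

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and pd.isna(x)):
            return ""
        if isinstance(x, float):
            return float_fmt.format(x)
        return str(x)

    header = "| " + " | ".join(str(c) for c in frame.columns) + " |"
    rule = "|" + "|".join("---" for _ in frame.columns) + "|"
    body = [
        "| " + " | ".join(fmt(v) for v in row) + " |"
        for row in frame.itertuples(index=False)
    ]
    return "\n".join([header, rule, *body])


def render_report(result: PipelineResult) -> str:
    """Deterministic Markdown report mirroring the survey-style tables."""
    cfg = result.config
    lines = [
        "# Pharmaceutical source/sink pipeline report",
        "",
        "## Configuration",
        "",
        f"- censored sediment values treated as point estimates: "
        f"{cfg.censored_as_point}",
        f"- wastewater production: {cfg.wastewater_L_per_capita_day:g} "
        "L/capita/day (configured default, not a measurement)",
        f"- region population: {cfg.region_population}",
        f"- risk assessment site: {cfg.risk_site}",
        "",
    ]
    if result.loads is not None:
        lines += ["## Consumption and expected influent", "",
                  markdown_table(result.loads), ""]
    if result.removal is not None:
        lines += [
            "## Removal efficiency (%)",
            "",
            "Integer percent; negative values mean effluent exceeded "
            "influent; no hydraulic-retention-time correction is applied to "
            "grab samples (known limitation).",
            "",
            markdown_table(result.removal),
            "",
        ]
    if result.partition is not None:
        note = (
            "Censored sediment bounds read as point estimates."
            if cfg.censored_as_point
            else "Censored sediment bounds propagated to bound-qualified K_d."
        )
        lines += ["## Sediment-water partitioning", "", note, "",
                  markdown_table(result.partition, "{:.4g}"), ""]
    if result.risk is not None:
        lines += [
            "## Aquatic risk quotients",
            "",
            f"MEC = surface water at {cfg.risk_site}; PNEC = most sensitive "
            "endpoint / assessment factor (NOEC: 10, LOEC: 20); RQ < 1 read "
            "as single-substance risk unlikely.  Mixture effects are out of "
            "scope.",
            "",
            markdown_table(result.risk, "{:.4g}"),
            "",
        ]
    if result.warnings:
        lines += ["## Warnings", ""]
        lines += [f"- {w}" for w in result.warnings]
        lines += [""]
    return "\n".join(lines)


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in [
        ("load_estimates.csv", result.loads),
        ("removal_table.csv", result.removal),
        ("partition_results.csv", result.partition),
        ("risk_table.csv", result.risk),
    ]:
        if frame is not None:
            # the removal matrix keeps its compound index; flat tables do not
            frame.to_csv(outdir / name, index=name == "removal_table.csv")
            written[name] = True
        else:
            written[name] = False
    (outdir / "report.md").write_text(render_report(result))
    manifest = {
        "generator": f"pharmfate {__version__}",
        "written": written,
        "complete": all(written.values()),
        "warnings": result.warnings,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
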