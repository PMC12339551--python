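"""End-to-end orchestration: design → simulate/ingest → necromass → compare.

One :func:`run_pipeline` call persists every intermediate table (recipe
design, per-sample necromass estimates, group summaries with compact
letters, depth contrasts) plus a human-readable run report echoing all
parameters and the constants version, so a run is reproducible from its
output directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import enzyme_stoich, group_stats, io, necromass, stoich_design
from .constants import CONSTANTS_VERSION
from .synthetic_data import GeneratorConfig, generate

log = logging.getLogger("necrostoich")

ENZYME_COLS = ("bg", "cbh", "nag", "lap", "ap")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either an input CSV or a simulation."""

    output_dir: str | Path
    input_csv: str | Path | None = None
    simulate: bool = False
    seed: int = 0
    noise_cv: float = 0.1
    n_replicates: int = 3
    group_by: tuple[str, ...] = ("treatment", "depth", "day")
    alpha: float = 0.05
    design: bool = True
    responses: tuple[str, ...] = ("bnc", "fnc", "mnc", "pnc",
                                  "mnc_soc_pct", "pnc_soc_pct")

    def __post_init__(self):
        if self.input_csv is None and not self.simulate:
            raise PipelineError("need either input_csv or simulate=True")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")


def _version() -> str:
    try:
        return metadata.version("necrostoich")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a report dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": _version(),
        "constants_version": CONSTANTS_VERSION,
        "seed": config.seed,
        "alpha": config.alpha,
        "outputs": {},
    }

    if config.design:
        recipes = stoich_design.design_table()
        io.write_csv(recipes, outdir / "amendment_recipes.csv")
        report["outputs"]["amendment_recipes"] = "amendment_recipes.csv"
        log.info("wrote amendment design table (%d treatments)", len(recipes))

    if config.simulate:
        gen = GeneratorConfig(seed=config.seed, noise_cv=config.noise_cv,
                              n_replicates=config.n_replicates)
        records = generate(gen)
        io.write_csv(records, outdir / "simulated_biomarkers.csv")
        report["outputs"]["biomarkers"] = "simulated_biomarkers.csv"
        report["source"] = f"simulated (seed={config.seed}, "
        report["source"] += f"noise_cv={config.noise_cv})"
    else:
        records = io.read_biomarker_csv(config.input_csv)
        report["source"] = str(config.input_csv)
    report["n_records"] = len(records)
    log.info("processing %d biomarker records", len(records))

    estimates = necromass.process_table(records)
    if all(c in estimates.columns for c in ENZYME_COLS):
        estimates = enzyme_stoich.add_ratios(estimates)
    io.write_csv(estimates, outdir / "necromass_estimates.csv")
    report["outputs"]["estimates"] = "necromass_estimates.csv"
    report["n_fnc_clamped"] = int(estimates["fnc_clamped"].sum())

    summary = necromass.summarize(estimates, by=list(config.group_by))
    io.write_csv(summary, outdir / "group_summary.csv")
    report["outputs"]["summary"] = "group_summary.csv"

    responses = [r for r in config.responses if r in estimates.columns]
    within = [k for k in config.group_by if k != "treatment"]
    letters, contrasts = group_stats.compare_table(
        estimates, responses, group="treatment", within=within,
        alpha=config.alpha,
    )
    io.write_csv(letters, outdir / "treatment_letters.csv")
    io.write_csv(contrasts, outdir / "depth_contrasts.csv")
    report["outputs"]["letters"] = "treatment_letters.csv"
    report["outputs"]["contrasts"] = "depth_contrasts.csv"

    _write_report(report, config, outdir / "run_report.txt")
    report["outputs"]["report"] = "run_report.txt"
    return report


def _write_report(report: dict, config: RunConfig, path: Path) -> None:
    lines = [
        "necrostoich run report",
        "======================",
        f"package version:   {report['package_version']}",
        f"constants version: {report['constants_version']}",
        f"input source:      {report['source']}",
        f"records processed: {report['n_records']}",
        f"FNC clamped:       {report['n_fnc_clamped']} record(s)",
        f"grouping keys:     {', '.join(config.group_by)}",
        f"alpha:             {config.alpha}",
        f"seed:              {config.seed}",
        "",
        "outputs:",
    ]
    lines += [f"  {k}: {v}" for k, v in report["outputs"].items()]
    path.write_text("\n".join(lines) + "\n")


def run_from_yaml(config_path: str | Path) -> dict:
    """Build a :class:`RunConfig` from a YAML mapping and run it."""
    raw = io.load_yaml(config_path)
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("group_by", "responses"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return run_pipeline(RunConfig(**raw))
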