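"""End-to-end pipeline orchestration.

A run executes, as requested: simulate -> lipid QC -> class statistics ->
cardiac derivation/summary -> stereology & expression quantification, and
writes every artifact as delimited text plus a JSON run manifest (config echo,
seed, library versions).  Identical config and seed reproduce identical output
byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cardiac import derive_cardiac, summarize_cardiac
from .errors import ConfigError
from .io import (CT_SCHEMA, ECHO_SCHEMA, GRID_SCHEMA, PEAK_SCHEMA,
                 read_table, write_table)
from .qc import QCConfig, clean_peaks
from .quantify import ddct_relative_expression, mito_per_field, volume_density
from .simulate import (EchoSimConfig, LipidSimConfig, generate_ct_table,
                       generate_echo_table, generate_grid_counts,
                       generate_peak_table)
from .stats import ComparisonSpec, FamilyConfig, build_report, class_tests

log = logging.getLogger("cardiolipidomics")

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "qc", "stats", "echo", "quant")


class GridSimParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_fields: int = Field(default=12, ge=1)
    density: float = Field(default=0.33, ge=0.0, le=1.0)
    grid_points: int = Field(default=400, ge=1)


class PipelineConfig(BaseModel):
    """Run configuration: inputs either simulated or read from paths."""

    model_config = ConfigDict(frozen=True)

    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is False
    peaks_path: str | None = None
    echo_path: str | None = None
    grid_path: str | None = None
    ct_path: str | None = None
    # stage configs
    lipid_sim: LipidSimConfig = Field(default_factory=LipidSimConfig)
    echo_sim: EchoSimConfig | None = None
    grid_sim: GridSimParams = Field(default_factory=GridSimParams)
    qc: QCConfig = Field(default_factory=QCConfig)
    family: FamilyConfig = Field(default_factory=FamilyConfig)
    comparisons: tuple[str, ...] = ("HET_vs_WT", "KO_vs_WT")
    control_genotype: str = "WT"


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _load_or_simulate(config: PipelineConfig, out: Path):
    seeds = _child_seeds(config.seed, 4)
    if config.simulate:
        peaks = generate_peak_table(config.lipid_sim.model_copy(update={"seed": seeds[0]}))
        echo_cfg = config.echo_sim or EchoSimConfig.from_presets()
        echo = generate_echo_table(echo_cfg.model_copy(update={"seed": seeds[1]}))
        grid = generate_grid_counts(config.grid_sim.n_fields, config.grid_sim.density,
                                    config.grid_sim.grid_points, seed=seeds[2])
        ct = generate_ct_table(seed=seeds[3])
        for name, df in (("peaks", peaks), ("echo", echo), ("grid_counts", grid),
                         ("ct", ct)):
            write_table(df, out / f"{name}.tsv")
        return peaks, echo, grid, ct
    tables = []
    for path, schema, label in ((config.peaks_path, PEAK_SCHEMA, "peaks"),
                                (config.echo_path, ECHO_SCHEMA, "echo"),
                                (config.grid_path, GRID_SCHEMA, "grid"),
                                (config.ct_path, CT_SCHEMA, "ct")):
        if path is None:
            tables.append(None)
            continue
        if not Path(path).exists():
            raise ConfigError(f"{label} input file not found: {path}")
        tables.append(read_table(path, schema))
    return tuple(tables)


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = ALL_STAGES) -> dict[str, Path]:
    """Execute the requested stages; returns a name -> path map of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    peaks, echo, grid, ct = _load_or_simulate(config, out)

    if "qc" in stages or "stats" in stages:
        if peaks is None:
            raise ConfigError("lipid stages requested but no peak table available")
        log.info("QC: cleaning %d peaks", len(peaks))
        profiles, report = clean_peaks(peaks, config.qc)
        log.info("QC: %s", report)
        artifacts["profiles"] = write_table(profiles, out / "species_profiles.tsv")
        (out / "qc_report.json").write_text(json.dumps(report.__dict__, indent=2))
        artifacts["qc_report"] = out / "qc_report.json"
        if "stats" in stages:
            comparisons = [ComparisonSpec.from_label(c) for c in config.comparisons]
            classes = list(config.lipid_sim.classes) if config.simulate else None
            results = class_tests(profiles, comparisons, config.family, classes)
            artifacts["class_results"] = write_table(results, out / "class_results.tsv")
            report_tbl = build_report(results, classes, config.comparisons)
            artifacts["class_report"] = write_table(report_tbl, out / "class_report.tsv")

    if "echo" in stages:
        if echo is None:
            raise ConfigError("echo stage requested but no echo table available")
        derived = derive_cardiac(echo)
        artifacts["cardiac_derived"] = write_table(derived, out / "cardiac_derived.tsv")
        summary = summarize_cardiac(derived)
        artifacts["cardiac_summary"] = write_table(summary, out / "cardiac_summary.tsv")

    if "quant" in stages:
        quant: dict[str, object] = {}
        if grid is not None:
            quant["mito_volume_density"] = volume_density(grid)
            quant["mito_mean_points_per_field"] = mito_per_field(grid["points_mito"])
        if ct is not None:
            rq = ddct_relative_expression(ct, config.control_genotype)
            artifacts["expression"] = write_table(rq, out / "expression.tsv")
            quant["rq_group_means"] = (
                rq.groupby("genotype", sort=False)["rq"].mean().round(6).to_dict())
        (out / "quant_summary.json").write_text(json.dumps(quant, indent=2))
        artifacts["quant_summary"] = out / "quant_summary.json"

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "config": json.loads(config.model_dump_json()),
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
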