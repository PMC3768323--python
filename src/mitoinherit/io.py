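"""Configuration parsing, tabular output and run manifests.

Configs are YAML (or any mapping) with two blocks: ``experiment`` (which
driver to run) and ``params`` (ModelParams fields).  All tabular output is
TSV — UTF-8, tab-separated, '.' decimal, 12 significant digits — so results
diff cleanly and round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .experiments import EquilibriumReport, Trajectory
from .params import FitnessSpec, InvalidParameterError, ModelParams, SwitchingSchedule

log = logging.getLogger("mitoinherit")

EXPERIMENTS = ("invasion", "forced_frequency", "sweep", "mating_types", "coadaptation")

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """A fully validated experiment configuration."""

    experiment: str
    params: ModelParams
    output_dir: Path = Path(".")
    report_every: int = 1
    scenario: Optional[str] = None  # mating_types
    pA_grid: Optional[list] = None  # forced_frequency
    grid: Optional[Dict[str, list]] = None  # sweep
    extras: Dict[str, object] = field(default_factory=dict)


_PARAM_FIELDS = {f.name for f in dc_fields(ModelParams)}


def parse_config(source: str | Dict) -> RunConfig:
    """Parse and validate a config document, applying documented defaults.

    Every field left at its default is logged, unknown keys raise a
    descriptive error naming the key.
    """
    doc = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    if not isinstance(doc, dict):
        raise InvalidParameterError("config must be a mapping")
    doc = dict(doc)
    experiment = doc.pop("experiment", None)
    if experiment not in EXPERIMENTS:
        raise InvalidParameterError(
            f"config key 'experiment' must be one of {EXPERIMENTS}, got {experiment!r}"
        )
    raw_params = dict(doc.pop("params", {}))
    if "fitness" in raw_params and not isinstance(raw_params["fitness"], FitnessSpec):
        raw_params["fitness"] = FitnessSpec(shape=str(raw_params["fitness"]))
    if "switching" in raw_params and raw_params["switching"] is not None:
        sw = raw_params["switching"]
        if not isinstance(sw, SwitchingSchedule):
            raw_params["switching"] = SwitchingSchedule(**sw)
    unknown = set(raw_params) - _PARAM_FIELDS
    if unknown:
        raise InvalidParameterError(
            f"unknown model parameter key(s): {sorted(unknown)}"
        )
    params = ModelParams(**raw_params)
    for f in dc_fields(ModelParams):
        if f.name not in raw_params:
            log.info("config: parameter %s defaulted to %r", f.name, getattr(params, f.name))

    cfg = RunConfig(
        experiment=experiment,
        params=params,
        output_dir=Path(doc.pop("output_dir", ".")),
        report_every=int(doc.pop("report_every", 1)),
        scenario=doc.pop("scenario", None),
        pA_grid=doc.pop("pA_grid", None),
        grid=doc.pop("grid", None),
    )
    if cfg.report_every < 1:
        raise InvalidParameterError("report_every must be >= 1")
    if doc:
        raise InvalidParameterError(f"unknown config key(s): {sorted(doc)}")
    if cfg.experiment == "mating_types" and cfg.scenario is None:
        raise InvalidParameterError("mating_types experiment requires 'scenario'")
    if cfg.experiment == "forced_frequency" and not cfg.pA_grid:
        raise InvalidParameterError("forced_frequency experiment requires 'pA_grid'")
    if cfg.experiment == "sweep" and not cfg.grid:
        raise InvalidParameterError("sweep experiment requires 'grid'")
    return cfg


def trajectory_frame(traj: Trajectory, report_every: int = 1) -> pd.DataFrame:
    df = traj.to_dataframe()
    if report_every > 1:
        df = df.iloc[::report_every].reset_index(drop=True)
    return df


def write_trajectory(traj: Trajectory, path: Path | str, report_every: int = 1) -> None:
    """TSV trajectory: one row per recorded generation."""
    df = trajectory_frame(traj, report_every)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trajectory(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def report_frame(reports: list[EquilibriumReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "p_A": r.p_A,
            "classification": r.classification,
            "c": r.c if r.c is not None else np.nan,
            "stable": r.stable,
            "converged": r.converged,
            "generations_to_converge": r.generations_to_converge,
            "Fbar_aa": r.mean_fitness.get("aa", np.nan),
            "Fbar_Aa": r.mean_fitness.get("Aa", np.nan),
            "Fbar_AA": r.mean_fitness.get("AA", np.nan),
            "Fbar_pop": r.mean_fitness_pop,
            "freq_aa": r.genotype_freqs.get("aa", 0.0),
            "freq_Aa": r.genotype_freqs.get("Aa", 0.0),
            "freq_AA": r.genotype_freqs.get("AA", 0.0),
        }
        for lab, f in sorted(r.haplotype_freqs.items()):
            row[f"freq_hap_{lab}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def write_equilibrium_report(
    reports: list[EquilibriumReport], path: Path | str
) -> None:
    """TSV equilibrium report: one row per run/sweep point."""
    report_frame(reports).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_manifest(cfg: RunConfig, path: Path | str) -> None:
    """Echo the configuration and library versions next to every result."""
    manifest = {
        "mitoinherit": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "experiment": cfg.experiment,
        "scenario": cfg.scenario,
        "report_every": cfg.report_every,
        "params": {
            f.name: _jsonable(getattr(cfg.params, f.name))
            for f in dc_fields(ModelParams)
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(v):
    if isinstance(v, FitnessSpec):
        return v.shape
    if isinstance(v, SwitchingSchedule):
        return {"period": v.period, "cost": v.cost}
    return v


__all__ = [
    "EXPERIMENTS",
    "RunConfig",
    "parse_config",
    "read_trajectory",
    "report_frame",
    "trajectory_frame",
    "write_equilibrium_report",
    "write_manifest",
    "write_trajectory",
]
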