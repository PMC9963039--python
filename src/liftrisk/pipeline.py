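"""End-to-end pipeline: generate -> idealize -> train -> convert -> simulate -> evaluate.

The trunk condition is trained first, then trunk+force, mirroring the study
workflow.  Every output file records the configuration hash and seed, and a
fixed seed reproduces every intermediate and final artifact bit-for-bit on
one platform.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimate, evaluate, generator, workday
from .config import RunConfig
from .generator import FORCE_CHANNELS, TARGET_CHANNEL, TRUNK_CHANNELS

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    config: RunConfig
    profiles: list
    trials: list
    manifest: pd.DataFrame
    lookup: pd.DataFrame
    workdays: pd.DataFrame
    summary: dict
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in memory and return all intermediates."""
    config.validate()
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    t0 = _stage("generate")
    profiles = generator.sample_participants(
        config.n_participants, config.anthro, seed=config.seed
    )
    tasks = generator.build_task_grid(
        config.tasks.mass_range_kg,
        config.tasks.height_range_cm,
        config.tasks.n_masses,
        config.tasks.n_heights,
        config.tasks.repetitions,
    )
    trials, manifest = generator.generate_dataset(profiles, tasks, config.sim, seed=config.seed)
    timings["generate"] = time.perf_counter() - t0

    t0 = _stage("train")
    predictions = {}
    for condition in estimate.CONDITIONS:  # trunk first, then trunk_force
        predictions[condition] = estimate.lopo_cross_validate(
            trials, condition, config.estimator, seed=config.seed
        )
    timings["train"] = time.perf_counter() - t0

    t0 = _stage("convert")
    lookup = estimate.build_lookup(trials, profiles, predictions, g=config.sim.gravity_ms2)
    timings["convert"] = time.perf_counter() - t0

    t0 = _stage("simulate")
    workdays = workday.run_simulation(
        lookup,
        n_days=config.workday.n_days,
        seed=config.seed,
        config=config.workday,
        grouping=config.eq4_grouping,
    )
    timings["simulate"] = time.perf_counter() - t0

    t0 = _stage("evaluate")
    summary = evaluate.summarize(workdays, band=config.band_pct)
    summary["config_hash"] = config.config_hash()
    summary["seed"] = config.seed
    summary["moment_type"] = config.workday.moment_type
    summary["eq4_grouping"] = config.eq4_grouping
    timings["evaluate"] = time.perf_counter() - t0
    for name, dt in timings.items():
        logger.info("stage %-9s %.2f s", name, dt)

    return PipelineResult(config, profiles, trials, manifest, lookup, workdays, summary, timings)


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline and persist every output under ``out_dir``.

    Writes the verbatim config, the trial manifest (and per-trial CSVs when
    ``config.write_trials``), the peak-moment lookup, the workday table, and
    ``summary.json``.  Any stage failure aborts with the stage name; outputs
    produced before the failure are left on disk for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "generate"
    try:
        result = run_pipeline(config)
        stage = "write"
        if config.write_trials:
            tdir = out / "trials"
            tdir.mkdir(exist_ok=True)
            for trial in result.trials:
                trial.to_dataframe().to_csv(
                    tdir / f"{trial.trial_id}.csv", index=False, float_format="%.9g"
                )
        meta = {"config_hash": config.config_hash(), "seed": config.seed}
        manifest = result.manifest.copy()
        for k, v in meta.items():
            manifest[k] = v
        manifest.to_csv(out / "manifest.csv", index=False, float_format="%.9g")
        lookup = result.lookup.copy()
        for k, v in meta.items():
            lookup[k] = v
        lookup.to_csv(out / "lookup.csv", index=False, float_format="%.9g")
        workdays = result.workdays.copy()
        for k, v in meta.items():
            workdays[k] = v
        workdays.to_csv(out / "workdays.csv", index=False, float_format="%.9g")
        (out / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc
    return out


TRIAL_REQUIRED = ["time_s"] + TRUNK_CHANNELS + FORCE_CHANNELS + [TARGET_CHANNEL]
LOOKUP_REQUIRED = estimate.LOOKUP_COLUMNS


def validate_inputs(path: str | Path) -> list[str]:
    """Validate a user-supplied trial or lookup CSV against the schema.

    Returns a list of violations (empty = clean).  The file kind is inferred
    from its columns: a table with a ``time_s`` column is treated as a trial,
    one with ``peak_load_lab`` as a lookup, a ``trial_id``+``file`` table as
    a manifest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise OSError(f"unreadable file {path}: {exc}") from exc
    violations: list[str] = []
    if "time_s" in df.columns:
        for col in TRIAL_REQUIRED:
            if col not in df.columns:
                violations.append(f"missing trial column: {col}")
        if "time_s" in df.columns and len(df) > 2:
            dt = np.diff(df["time_s"].to_numpy())
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                violations.append("time_s: non-uniform timestamps")
        for col in df.columns:
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()[:5]
                violations.append(f"{col}: missing values at rows {rows}")
    elif "peak_load_lab" in df.columns or "peak_lumbar_lab" in df.columns:
        for col in LOOKUP_REQUIRED:
            if col not in df.columns:
                violations.append(f"missing lookup column: {col}")
    elif {"trial_id", "file"} <= set(df.columns):
        for col in ("participant_id", "task_id", "repetition", "box_mass_kg", "origin_height_cm"):
            if col not in df.columns:
                violations.append(f"missing manifest column: {col}")
    else:
        violations.append("unrecognised table: expected a trial, lookup, or manifest CSV")
    return violations
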