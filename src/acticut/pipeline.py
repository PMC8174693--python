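"""Pipeline driver: simulate -> derive -> validate, with provenance.

`build_study_dataset` turns simulated sessions into the canonical long
observation table (one row per participant x stage x placement, with the
last-minute VM and ENMO values and the last-two-minute VO2 mean);
`run_pipeline` wires the stages together and writes all artifacts plus a
provenance manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .agreement import build_validation_report, classify_observations
from .cohort import (
    ConfigurationError,
    SimulatedSession,
    SimulationConfig,
    simulate_cohort,
)
from .cutpoints import derive_cutpoints
from .metabolic import classify_intensity, stage_mean_vo2, vo2_to_met
from .signal import InsufficientDataError, stage_last_minute_value

__all__ = [
    "PipelineConfig",
    "build_study_dataset",
    "melt_metrics",
    "run_pipeline",
    "summarize_sample",
]

logger = logging.getLogger("acticut")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    vo2_window_s: float = 120.0
    report_format: str = "csv"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        sim = SimulationConfig()
        for key, val in sim_raw.items():
            if not hasattr(sim, key):
                raise ConfigurationError(f"unknown simulation option {key!r}")
            setattr(sim, key, val)
        cfg = cls(simulation=sim)
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown pipeline option {key!r}")
            setattr(cfg, key, val)
        return cfg

    def digest(self) -> str:
        """Stable hash of the full configuration for the manifest."""

        def jsonable(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return jsonable(dataclasses.asdict(o))
            if isinstance(o, dict):
                return {str(k): jsonable(v) for k, v in sorted(
                    o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [jsonable(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o if isinstance(o, (str, int, float, bool, type(None))) else str(o)

        blob = json.dumps(jsonable(dataclasses.asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_study_dataset(
    sessions: list[SimulatedSession], vo2_window_s: float = 120.0
) -> pd.DataFrame:
    """Long observation table from simulated sessions.

    Per stage and placement: VM counts/min and ENMO mg/min from the last
    minute of the stage, VO2 from the last two minutes of breaths.
    Dropped (missing) stage records are skipped, mirroring incomplete
    real collections.
    """
    rows = []
    for sess in sessions:
        p = sess.participant
        for rec in sess.stages:
            if rec.dropped:
                continue
            vo2 = stage_mean_vo2(sess.vo2, rec.stage, vo2_window_s)
            for placement in sorted(set(rec.counts_1s) | set(rec.enmo_1s)):
                try:
                    vm = (stage_last_minute_value(rec.counts_series(placement),
                                                  rec.stage)
                          if placement in rec.counts_1s else np.nan)
                    enmo = (stage_last_minute_value(rec.enmo_series(placement),
                                                    rec.stage)
                            if placement in rec.enmo_1s else np.nan)
                except InsufficientDataError:
                    continue
                rows.append({
                    "participant": p.id, "sex": p.sex, "age": p.age,
                    "activity": rec.stage.label,
                    "stage_type": rec.stage.stage_type,
                    "placement": placement,
                    "vm_counts": vm, "enmo_mg": enmo, "vo2": vo2,
                })
    df = pd.DataFrame(rows)
    df["met"] = df["vo2"] / 3.5
    return df


def melt_metrics(dataset: pd.DataFrame) -> pd.DataFrame:
    """Wide (vm_counts, enmo_mg columns) -> long (metric, metric_value)."""
    id_vars = [c for c in dataset.columns if c not in ("vm_counts", "enmo_mg")]
    long = dataset.melt(id_vars=id_vars, value_vars=["vm_counts", "enmo_mg"],
                        var_name="metric", value_name="metric_value")
    return long


def _reference_intensity(dataset: pd.DataFrame) -> pd.Series:
    return dataset["met"].map(
        lambda m: classify_intensity(float(m)) if pd.notna(m) else np.nan
    )


def summarize_sample(participants, dataset: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: mean (sd) by sex and total.

    Rows cover age, height, mass, BMI, VO2 while reading, and the MET of
    each everyday activity; columns male / female / total.
    """
    demo = pd.DataFrame([
        {"participant": p.id, "sex": p.sex, "age": p.age,
         "height_cm": p.height_cm, "mass_kg": p.mass_kg, "bmi": p.bmi}
        for p in participants
    ])
    per_pa = dataset.drop_duplicates(["participant", "activity"])
    rows = []

    def add_row(label, series_by_pid):
        merged = demo[["participant", "sex"]].merge(series_by_pid, on="participant")
        col = merged.columns[-1]
        entry = {"variable": label}
        for grp, sub in (("male", merged[merged.sex == "male"]),
                         ("female", merged[merged.sex == "female"]),
                         ("total", merged)):
            entry[f"{grp}_mean"] = float(sub[col].mean()) if len(sub) else np.nan
            entry[f"{grp}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(entry)

    for var in ("age", "height_cm", "mass_kg", "bmi"):
        add_row(var, demo[["participant", var]])
    reading = per_pa[per_pa.activity == "reading"][["participant", "vo2"]]
    if len(reading):
        add_row("vo2_reading", reading)
    for act in per_pa[per_pa.stage_type == "everyday"]["activity"].unique():
        sub = per_pa[per_pa.activity == act][["participant", "met"]]
        add_row(f"met_{act}", sub.rename(columns={"met": f"met_{act}"}))
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    mode: str,
    out_dir,
    input_path=None,
    cutpoints_path=None,
) -> dict:
    """Run one or all pipeline stages and write artifacts under ``out_dir``.

    Modes: ``simulate`` (write the synthetic dataset), ``derive``
    (cut-point tables from treadmill observations), ``validate``
    (classification report from everyday observations plus a cut-point
    table), ``full`` (all three). Returns a manifest dict also written
    as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    caught: list[str] = []
    artifacts: dict[str, str] = {}
    fmt = config.report_format

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        dataset = None
        if mode in ("simulate", "full"):
            logger.info("simulating cohort (n=%d, seed=%d)",
                        config.simulation.n_participants, config.simulation.seed)
            sessions = simulate_cohort(config.simulation)
            dataset = build_study_dataset(sessions, config.vo2_window_s)
            aio.write_study_dataset(dataset, out / "dataset.csv")
            artifacts["dataset"] = "dataset.csv"
            summary = summarize_sample([s.participant for s in sessions], dataset)
            summary.to_csv(out / "sample_summary.csv", index=False)
            artifacts["sample_summary"] = "sample_summary.csv"

        if mode in ("derive", "full"):
            if dataset is None:
                if input_path is None:
                    raise FileNotFoundError("derive needs --input (dataset file)")
                dataset = aio.read_study_dataset(input_path)
            treadmill = dataset[dataset.stage_type == "treadmill"]
            obs = melt_metrics(treadmill)
            logger.info("deriving cut-points from %d treadmill observations", len(obs))
            models, reports = derive_cutpoints(obs, config.alpha)
            aio.write_cutpoints(models, out / "cutpoints.csv", "csv")
            aio.write_cutpoints(models, out / "cutpoints.json", "json")
            pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
                out / "confounding.csv", index=False)
            artifacts.update({"cutpoints": "cutpoints.csv",
                              "confounding": "confounding.csv"})

        if mode in ("validate", "full"):
            if dataset is None:
                if input_path is None:
                    raise FileNotFoundError("validate needs --input (dataset file)")
                dataset = aio.read_study_dataset(input_path)
            if mode == "validate":
                cp_file = cutpoints_path or (out / "cutpoints.csv")
                if not Path(cp_file).exists():
                    raise FileNotFoundError(
                        f"no cut-point table at {cp_file}; run derive first"
                    )
                models = aio.read_cutpoints(cp_file)
            everyday = dataset[dataset.stage_type == "everyday"].copy()
            everyday["reference_intensity"] = _reference_intensity(everyday)
            classified = classify_observations(melt_metrics(everyday), models)
            report = build_validation_report(classified)
            aio.write_validation_report(report, out / "validation_report.json", "json")
            report.proportions.to_csv(out / "confusion_proportions.csv", index=False)
            artifacts.update({"validation_report": "validation_report.json",
                              "confusion_proportions": "confusion_proportions.csv"})

        caught = sorted({str(w.message) for w in wlist})

    import acticut

    manifest = {
        "mode": mode,
        "seed": config.simulation.seed,
        "config_digest": config.digest(),
        "alpha": config.alpha,
        "version": acticut.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "artifacts": artifacts,
        "warnings": caught,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
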