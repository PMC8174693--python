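"""Readers and writers for the pipeline's text formats.

Raw signals travel as ActiGraph-style CSV (a 10-line header block, then
one sample per row with the three axis columns in g); 1-s epoch counts
as timestamped CSV; study observations as a long-table CSV (optionally
an SPSS .sav export when pyreadstat is installed); cut-point tables and
validation reports as CSV/JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cutpoints import CutpointModel
from .signal import RawTriaxialSignal

__all__ = [
    "write_actigraph_raw_csv",
    "read_actigraph_raw_csv",
    "write_epoch_csv",
    "read_epoch_csv",
    "DATASET_COLUMNS",
    "write_study_dataset",
    "read_study_dataset",
    "SchemaError",
    "write_cutpoints",
    "read_cutpoints",
    "write_validation_report",
]

_RAW_HEADER_LINES = 10

#: canonical long-table columns: one row per participant x stage x placement
DATASET_COLUMNS = [
    "participant", "sex", "age", "activity", "stage_type", "placement",
    "vm_counts", "enmo_mg", "vo2",
]

#: accepted aliases (lower-cased) for tolerant column mapping
_ALIASES = {
    "participant": ["participant", "id", "subject", "subject_id", "pid"],
    "sex": ["sex", "gender"],
    "age": ["age", "age_years", "age_y"],
    "activity": ["activity", "stage", "task", "activity_label"],
    "stage_type": ["stage_type", "part", "protocol_part", "type"],
    "placement": ["placement", "position", "site", "location"],
    "vm_counts": ["vm_counts", "vm", "vector_magnitude", "counts_vm", "vm_per_min"],
    "enmo_mg": ["enmo_mg", "enmo", "enmo_mg_per_min"],
    "vo2": ["vo2", "vo2_mlkgmin", "oxygen_uptake", "vo2_ml_kg_min"],
}


class SchemaError(ValueError):
    """Input table cannot be mapped onto the expected columns."""


def write_actigraph_raw_csv(signal: RawTriaxialSignal, path) -> None:
    """Raw CSV with a 10-line device-style header stub, then x,y,z in g."""
    path = Path(path)
    header = [
        "------------ Data File Created By Signal Writer ------------",
        f"Placement: {signal.placement}",
        f"Sample Rate: {signal.rate:g}",
        f"Start Time (s): {signal.start_time:g}",
        "Axes: X,Y,Z (g)",
        "Filter: none",
        "Mode: raw",
        "Firmware: synthetic",
        "Serial: SIMULATED",
        "-------------------------------------------------------------",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, signal.samples, delimiter=",", fmt="%.6f")


def read_actigraph_raw_csv(path) -> RawTriaxialSignal:
    """Read a raw CSV; tolerates presence or absence of the header block."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    placement, rate, start = "unknown", 30.0, 0.0
    skip = 0
    if first.startswith("---"):  # header block present
        skip = _RAW_HEADER_LINES
        with path.open() as fh:
            for line in (fh.readline() for _ in range(_RAW_HEADER_LINES)):
                if line.startswith("Placement:"):
                    placement = line.split(":", 1)[1].strip()
                elif line.startswith("Sample Rate:"):
                    rate = float(line.split(":", 1)[1])
                elif line.startswith("Start Time (s):"):
                    start = float(line.split(":", 1)[1])
    samples = np.loadtxt(path, delimiter=",", skiprows=skip)
    return RawTriaxialSignal(placement, rate, np.atleast_2d(samples), start)


def write_epoch_csv(counts: np.ndarray, path, start_time: float = 0.0) -> None:
    """1-s epoch counts as CSV: timestamp_s, axis1, axis2, axis3."""
    counts = np.asarray(counts)
    ts = start_time + np.arange(counts.shape[0], dtype=float)
    pd.DataFrame({
        "timestamp_s": ts,
        "axis1": counts[:, 0],
        "axis2": counts[:, 1],
        "axis3": counts[:, 2],
    }).to_csv(path, index=False)


def read_epoch_csv(path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    counts = df[["axis1", "axis2", "axis3"]].to_numpy()
    start = float(df["timestamp_s"].iloc[0]) if len(df) else 0.0
    return counts, start


def write_study_dataset(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False)


def _map_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    lower = {c.lower().strip(): c for c in df.columns}
    rename: dict[str, str] = {}
    unmapped: list[str] = []
    for canon in DATASET_COLUMNS:
        aliases = [a.lower() for a in _ALIASES[canon]]
        if column_map and canon in column_map:
            aliases = [column_map[canon].lower()] + aliases
        hit = next((lower[a] for a in aliases if a in lower), None)
        if hit is None:
            unmapped.append(canon)
        else:
            rename[hit] = canon
    if unmapped:
        raise SchemaError(
            f"missing required columns {unmapped}; accepted names: "
            + "; ".join(f"{c}: {_ALIASES[c]}" for c in unmapped)
        )
    return df.rename(columns=rename)


def read_study_dataset(path, column_map: dict | None = None) -> pd.DataFrame:
    """Long observation table from CSV or SPSS .sav.

    Column names are matched case-insensitively against known aliases,
    overridable through ``column_map`` (canonical name -> file column).
    Adds a derived ``met`` column (VO2 / 3.5).
    """
    path = Path(path)
    if path.suffix.lower() == ".sav":
        try:
            df = pd.read_spss(path)
        except ImportError as exc:  # pyreadstat not installed
            raise SchemaError(
                "SPSS support needs the optional pyreadstat package; "
                "export the file to CSV instead"
            ) from exc
    else:
        df = pd.read_csv(path)
    df = _map_columns(df, column_map)
    df = df[DATASET_COLUMNS].copy()
    df["sex"] = df["sex"].astype(str).str.lower()
    df["stage_type"] = df["stage_type"].astype(str).str.lower()
    bad = set(df["stage_type"].unique()) - {"treadmill", "everyday"}
    if bad:
        raise SchemaError(f"stage_type must be treadmill/everyday, found {sorted(bad)}")
    df["met"] = df["vo2"] / 3.5
    return df


def write_cutpoints(models: list[CutpointModel], path, fmt: str = "csv") -> None:
    from .cutpoints import cutpoints_to_frame

    frame = cutpoints_to_frame(models)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        Path(path).write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_cutpoints(path) -> list[CutpointModel]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict(orient="records")
    return [
        CutpointModel(
            r["placement"], r["metric"], r["stratum"], float(r["intercept"]),
            float(r["slope"]), float(r["cut_moderate"]), float(r["cut_vigorous"]),
            float(r["r_squared"]), int(r["n_obs"]),
        )
        for r in rows
    ]


def write_validation_report(report, path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2))
    elif fmt == "csv":
        report.proportions.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
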