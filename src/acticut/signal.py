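"""Raw tri-axial signal processing: auto-calibration, ENMO, epoch metrics.

Two per-minute metrics are produced from wearable output. Vector-magnitude
(VM) counts come from the device's per-axis 1-s activity counts via the
Euclidean norm and are summed to counts/min. ENMO (Euclidean Norm Minus
One) comes from the calibrated raw 30 Hz signal: per sample
``max(0, ||a|| - 1 g)``, averaged per 1-s epoch and expressed in mg; the
per-minute value is the mean of the sixty 1-s values.

Auto-calibration estimates per-axis offset and gain so that non-movement
("still") windows lie on the unit gravity sphere; when too few
orientation-diverse still windows exist, backup coefficients (or the
identity) are used instead, mirroring device-fleet practice.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolStage

__all__ = [
    "RawTriaxialSignal",
    "CalibrationCoefficients",
    "EpochSeries",
    "StillWindow",
    "vector_magnitude",
    "detect_still_windows",
    "autocalibrate",
    "apply_calibration",
    "compute_enmo",
    "aggregate_to_minute",
    "stage_last_minute_value",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a window/stage does not contain enough data."""


@dataclass
class RawTriaxialSignal:
    """Raw acceleration in g, shape (n_samples, 3), at ``rate`` Hz."""

    placement: str
    rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate


@dataclass
class CalibrationCoefficients:
    """Per-axis linear correction applied as ``gain * sample + offset``."""

    offset: np.ndarray
    gain: np.ndarray
    post_error: float
    source: str  # "autocalibrated" | "backup" | "identity"

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("gains must be strictly positive")
        if self.post_error < 0:
            raise ValueError("post_error must be non-negative")

    @classmethod
    def identity(cls) -> "CalibrationCoefficients":
        return cls(np.zeros(3), np.ones(3), 0.0, "identity")


@dataclass
class EpochSeries:
    """Per-epoch metric values for one placement."""

    placement: str
    metric: str  # "vm_counts" | "enmo_mg"
    epoch_length: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("epoch values must be non-negative")


@dataclass
class StillWindow:
    start_idx: int
    stop_idx: int  # exclusive
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]


def vector_magnitude(x, y, z):
    """Euclidean norm sqrt(x^2 + y^2 + z^2) of per-axis counts.

    Accepts scalars or arrays; inputs must be non-negative (counts).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if np.any(x < 0) or np.any(y < 0) or np.any(z < 0):
        raise ValueError("counts must be non-negative")
    out = np.sqrt(x * x + y * y + z * z)
    return float(out) if out.ndim == 0 else out


def detect_still_windows(
    signal: RawTriaxialSignal,
    window_s: float = 10.0,
    sd_threshold: float = 0.013,
) -> list[StillWindow]:
    """Find maximal non-movement windows.

    The signal is scanned in consecutive blocks of ``window_s``; blocks
    whose per-axis standard deviation is below ``sd_threshold`` on all
    three axes are marked still, and adjacent still blocks are merged
    into maximal windows. Each returned window carries its mean vector.
    """
    if window_s < 1.0:
        raise ValueError("window must be at least 1 s")
    n_block = int(round(window_s * signal.rate))
    n = signal.samples.shape[0]
    if n < n_block:
        return []
    n_full = n // n_block
    blocks = signal.samples[: n_full * n_block].reshape(n_full, n_block, 3)
    still = (blocks.std(axis=1) < sd_threshold).all(axis=1)

    windows: list[StillWindow] = []
    i = 0
    while i < n_full:
        if still[i]:
            j = i
            while j + 1 < n_full and still[j + 1]:
                j += 1
            start, stop = i * n_block, (j + 1) * n_block
            windows.append(
                StillWindow(start, stop, signal.samples[start:stop].mean(axis=0))
            )
            i = j + 1
        else:
            i += 1
    return windows


def _orientation_diverse(means: np.ndarray, min_windows: int, min_spread: float) -> bool:
    """Loose octant-coverage check: enough windows and, on every axis,
    window means on both sides of +/- ``min_spread``."""
    if means.shape[0] < min_windows:
        return False
    return bool(
        np.all(means.min(axis=0) < -min_spread) and np.all(means.max(axis=0) > min_spread)
    )


def autocalibrate(
    signal: RawTriaxialSignal,
    backup: CalibrationCoefficients | None = None,
    *,
    window_s: float = 10.0,
    sd_threshold: float = 0.013,
    min_windows: int = 10,
    min_spread: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CalibrationCoefficients:
    """Sphere-fit per-axis offset and gain from still windows.

    Iteratively regresses each still-window mean's projection onto the
    unit sphere against its current calibrated value, per axis,
    accumulating gain/offset until the post-calibration error (mean
    absolute deviation of calibrated still-window norms from 1 g)
    changes by less than ``tol`` g. Falls back to ``backup`` (or the
    identity, with a warning) when still windows are too few or not
    orientation-diverse.
    """
    wins = detect_still_windows(signal, window_s, sd_threshold)
    means = np.array([w.mean for w in wins]) if wins else np.empty((0, 3))
    if not _orientation_diverse(means, min_windows, min_spread):
        if backup is not None:
            return CalibrationCoefficients(
                backup.offset.copy(), backup.gain.copy(), backup.post_error, "backup"
            )
        warnings.warn(
            "insufficient orientation-diverse still windows; identity calibration used",
            stacklevel=2,
        )
        return CalibrationCoefficients.identity()

    gain = np.ones(3)
    offset = np.zeros(3)
    prev_err = np.inf
    for _ in range(max_iter):
        cal = means * gain + offset
        norms = np.linalg.norm(cal, axis=1)
        err = float(np.abs(norms - 1.0).mean())
        if abs(prev_err - err) < tol:
            break
        prev_err = err
        target = cal / norms[:, None]
        # per-axis LS: target ~ d + e * cal, then fold into cumulative coefs
        for ax in range(3):
            A = np.column_stack([np.ones(cal.shape[0]), cal[:, ax]])
            d, e = np.linalg.lstsq(A, target[:, ax], rcond=None)[0]
            gain[ax] *= e
            offset[ax] = offset[ax] * e + d
    cal = means * gain + offset
    post_error = float(np.abs(np.linalg.norm(cal, axis=1) - 1.0).mean())
    return CalibrationCoefficients(offset, gain, post_error, "autocalibrated")


def apply_calibration(
    signal: RawTriaxialSignal, coef: CalibrationCoefficients
) -> RawTriaxialSignal:
    """Map every sample to ``gain * sample + offset`` (per axis)."""
    return RawTriaxialSignal(
        signal.placement,
        signal.rate,
        signal.samples * coef.gain + coef.offset,
        signal.start_time,
    )


def compute_enmo(signal: RawTriaxialSignal) -> EpochSeries:
    """ENMO per 1-s epoch, in mg.

    Per sample ``max(0, ||a|| - 1)`` (negatives clipped before epoch
    averaging), then the per-epoch mean scaled by 1000. A trailing
    partial second is dropped with a warning.
    """
    rate = int(round(signal.rate))
    n = signal.samples.shape[0]
    n_full = n // rate
    if n_full * rate != n:
        warnings.warn("trailing partial second dropped from ENMO series", stacklevel=2)
    norms = np.linalg.norm(signal.samples[: n_full * rate], axis=1)
    enmo = np.clip(norms - 1.0, 0.0, None).reshape(n_full, rate).mean(axis=1)
    return EpochSeries(signal.placement, "enmo_mg", 1.0, enmo * 1000.0, signal.start_time)


def aggregate_to_minute(series: EpochSeries, mode: str) -> EpochSeries:
    """Aggregate 1-s epochs to 60-s epochs.

    ``sum_counts``: minute value is the sum over the sixty seconds
    (equivalently mean x 60). ``mean_mg``: minute value is the mean of
    the sixty 1-s mg values. An incomplete trailing minute is dropped.
    """
    if mode not in ("sum_counts", "mean_mg"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    per_min = int(round(60.0 / series.epoch_length))
    if per_min * series.epoch_length != 60.0:
        raise ValueError("epoch length must divide 60 s")
    n_min = series.values.shape[0] // per_min
    vals = series.values[: n_min * per_min].reshape(n_min, per_min)
    out = vals.sum(axis=1) if mode == "sum_counts" else vals.mean(axis=1)
    return EpochSeries(series.placement, series.metric, 60.0, out, series.start_time)


def stage_last_minute_value(series: EpochSeries, stage: ProtocolStage) -> float:
    """Per-minute metric value from the final 60 s of a stage.

    Counts are summed, mg values averaged, over the last sixty 1-s
    epochs that fall inside the stage window.
    """
    if series.epoch_length != 1.0:
        raise ValueError("stage extraction expects a 1-s epoch series")
    if stage.start_s is None:
        raise ValueError(f"stage {stage.label} has no start time")
    first = int(np.ceil(stage.start_s - series.start_time))
    last = int(np.floor(stage.end_s - series.start_time))
    last = min(last, series.values.shape[0])
    first = max(first, 0)
    if last - first < 60:
        raise InsufficientDataError(
            f"stage {stage.label}: only {max(last - first, 0)} s of overlap, need 60"
        )
    window = series.values[last - 60 : last]
    if series.metric == "vm_counts":
        return float(window.sum())
    return float(window.mean())
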