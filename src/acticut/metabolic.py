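"""Indirect-calorimetry reference: stage VO2 means, METs, intensity classes.

Breath-by-breath oxygen uptake (VO2, ml·kg⁻¹·min⁻¹) is the criterion
measure. Stage intensity is the mean VO2 over the final two minutes of
the stage, divided by 3.5 ml·kg⁻¹·min⁻¹ (the conventional 1-MET value),
and classified with half-open bins: <3 METs sedentary/light, 3–<6
moderate, ≥6 vigorous (boundaries belong to the upper class).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolStage
from .signal import InsufficientDataError

ML_O2_PER_MET = 3.5  # ml·kg⁻¹·min⁻¹ defining 1 MET


@dataclass
class CalorimetrySeries:
    """Breath-by-breath VO2 samples for one participant's session."""

    times: np.ndarray  # s, strictly increasing
    vo2: np.ndarray  # ml·kg⁻¹·min⁻¹, > 0
    participant: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.times.shape != self.vo2.shape:
            raise ValueError("times and vo2 must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breath times must be strictly increasing")
        if np.any(self.vo2 <= 0):
            raise ValueError("VO2 must be strictly positive")


@dataclass
class StageMetabolicResult:
    stage: str
    mean_vo2: float
    met: float
    intensity: str


def stage_mean_vo2(
    series: CalorimetrySeries, stage: ProtocolStage, window_s: float = 120.0
) -> float:
    """Mean VO2 of breaths in ``[stage_end - window, stage_end)``.

    For stages shorter than the window, the window shrinks to the stage
    duration with a warning. Breaths are not interpolated or weighted.
    """
    if stage.start_s is None:
        raise ValueError(f"stage {stage.label} has no start time")
    if window_s > stage.duration_s:
        warnings.warn(
            f"stage {stage.label}: window shrunk to stage duration "
            f"({stage.duration_s:.0f} s)",
            stacklevel=2,
        )
        window_s = stage.duration_s
    lo, hi = stage.end_s - window_s, stage.end_s
    mask = (series.times >= lo) & (series.times < hi)
    if not mask.any():
        raise InsufficientDataError(
            f"stage {stage.label}: no breath samples in final {window_s:.0f} s"
        )
    return float(series.vo2[mask].mean())


def vo2_to_met(mean_vo2: float) -> float:
    """MET = VO2 / 3.5 ml·kg⁻¹·min⁻¹."""
    if mean_vo2 < 0:
        raise ValueError("VO2 cannot be negative")
    return mean_vo2 / ML_O2_PER_MET


def classify_intensity(met: float) -> str:
    """Half-open MET bins; 3.0 is moderate, 6.0 is vigorous."""
    if met < 0:
        raise ValueError("MET cannot be negative")
    if met < 3.0:
        return "sedentary_light"
    if met < 6.0:
        return "moderate"
    return "vigorous"


def stage_result(
    series: CalorimetrySeries, stage: ProtocolStage, window_s: float = 120.0
) -> StageMetabolicResult:
    """Convenience: stage mean VO2 -> MET -> intensity in one record."""
    vo2 = stage_mean_vo2(series, stage, window_s)
    met = vo2_to_met(vo2)
    return StageMetabolicResult(stage.label, vo2, met, classify_intensity(met))
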