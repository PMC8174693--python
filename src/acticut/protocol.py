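"""Study protocol vocabulary: stages, placements, metrics, intensity levels.

The calibration protocol has two parts: an incremental treadmill walk
(3.0 to 5.0 km/h in 0.5 km/h steps of 4 min each, 1% grade) used to fit
the metric-on-VO2 regressions, and five staged everyday activities
(reading, cleaning, shopping, cycling, aerobics) used to validate the
derived cut-points. Accelerometers sit at six anatomical placements.
"""
from __future__ import annotations

from dataclasses import dataclass, field

TREADMILL_LABELS = (
    "treadmill_3.0",
    "treadmill_3.5",
    "treadmill_4.0",
    "treadmill_4.5",
    "treadmill_5.0",
)
EVERYDAY_LABELS = ("reading", "cleaning", "shopping", "cycling", "aerobics")

PLACEMENTS = (
    "ankle_dominant",
    "ankle_nondominant",
    "wrist_dominant",
    "wrist_nondominant",
    "hip_correct",
    "hip_erroneous",
)

METRICS = ("vm_counts", "enmo_mg")

INTENSITY_LEVELS = ("sedentary_light", "moderate", "vigorous")
#: ordinal coding used when intensity classes enter an ICC
INTENSITY_CODES = {"sedentary_light": 1, "moderate": 2, "vigorous": 3}


def placement_group(placement: str) -> str:
    """Anatomical site without laterality, e.g. ``ankle_dominant`` -> ``ankle``."""
    return placement.split("_", 1)[0]


@dataclass
class ProtocolStage:
    """One stage of the session protocol.

    ``target_met`` is the ground-truth metabolic intensity used by the
    simulator; for ingested real data it may stay ``None``. ``start_s``
    is the stage's offset from the session (or signal) origin, filled in
    when stages are laid out on a timeline.
    """

    label: str
    stage_type: str  # "treadmill" | "everyday"
    duration_s: float = 240.0
    target_met: float | None = None
    start_s: float | None = None

    def __post_init__(self) -> None:
        if self.stage_type not in ("treadmill", "everyday"):
            raise ValueError(f"unknown stage_type {self.stage_type!r}")
        if self.duration_s <= 0:
            raise ValueError("stage duration must be positive")
        if self.target_met is not None and self.target_met <= 0:
            raise ValueError("target_met must be positive")

    @property
    def end_s(self) -> float:
        if self.start_s is None:
            raise ValueError(f"stage {self.label} has no start time")
        return self.start_s + self.duration_s


def default_stages() -> list[ProtocolStage]:
    """The full session: reading first, treadmill ramp, remaining activities."""
    treadmill_mets = {"treadmill_3.0": 2.8, "treadmill_3.5": 3.2,
                      "treadmill_4.0": 3.6, "treadmill_4.5": 4.0,
                      "treadmill_5.0": 4.5}
    everyday_mets = {"reading": 0.94, "cleaning": 3.0, "shopping": 3.4,
                     "cycling": 4.7, "aerobics": 4.6}
    stages = [ProtocolStage("reading", "everyday", 240.0, everyday_mets["reading"])]
    stages += [ProtocolStage(lbl, "treadmill", 240.0, treadmill_mets[lbl])
               for lbl in TREADMILL_LABELS]
    stages += [ProtocolStage(lbl, "everyday", 240.0, everyday_mets[lbl])
               for lbl in EVERYDAY_LABELS if lbl != "reading"]
    t = 0.0
    for st in stages:
        st.start_s = t
        t += st.duration_s
    return stages
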