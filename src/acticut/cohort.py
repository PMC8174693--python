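"""Synthetic cohort and session generator with known ground truth.

Emulates a laboratory calibration study in older adults: 20 participants
(11 male / 9 female, ~59-73 y) each complete five 4-min treadmill stages
(3.0-5.0 km/h) and five staged everyday activities while wearing
accelerometers at six placements and a breath-by-breath calorimeter.

The generator works at two levels. The *analysis* level draws per-second
activity counts and ENMO values from a linear dose-response model
(metric/min = intercept + slope * VO2 + subject effect + noise) whose
default intercepts and slopes are anchored to published placement-
specific cut-point tables, so every downstream estimate has a known
analytic value. The *raw* level synthesises 30 Hz tri-axial signals
(gravity vector + oscillation + optional per-axis miscalibration and
still windows) to exercise the auto-calibration/ENMO chain; activity
counts are never derived from the raw signal because the device's count
filter is proprietary — counts are device output here, as in the study.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .metabolic import ML_O2_PER_MET, CalorimetrySeries
from .protocol import (
    EVERYDAY_LABELS,
    METRICS,
    PLACEMENTS,
    ProtocolStage,
    default_stages,
    placement_group,
)
from .signal import EpochSeries, RawTriaxialSignal

__all__ = [
    "ParticipantProfile",
    "MetricModel",
    "SimulationConfig",
    "StageRecord",
    "SimulatedSession",
    "ConfigurationError",
    "simulate_participants",
    "simulate_vo2_series",
    "simulate_epoch_metrics",
    "simulate_raw_signal",
    "simulate_calibration_session",
    "simulate_session",
    "simulate_cohort",
]

RESTING_VO2 = ML_O2_PER_MET  # 1-MET resting VO2, ml·kg⁻¹·min⁻¹
_AGE_CENTER = 63.0  # years; age slopes act on (age - center)


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class ParticipantProfile:
    id: str
    sex: str  # "male" | "female"
    age: int
    height_cm: float
    mass_kg: float
    dominant_side: str = "right"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.height_cm <= 0 or self.mass_kg <= 0:
            raise ValueError("height and mass must be positive")

    @property
    def bmi(self) -> float:
        """kg·m⁻², mass over squared height in metres."""
        return self.mass_kg / (self.height_cm / 100.0) ** 2


@dataclass
class MetricModel:
    """Linear dose-response of a per-minute metric on stage VO2.

    Sex offsets are added for female participants; the age slope acts on
    age centred at 63 y. ``between_sd`` is the per-participant random
    intercept sd, ``residual_sd`` the per-minute residual sd, both in
    minute-level metric units.
    """

    intercept: float
    slope: float  # metric units per ml·kg⁻¹·min⁻¹
    between_sd: float = 0.0
    residual_sd: float = 0.0
    sex_intercept_offset: float = 0.0
    sex_slope_offset: float = 0.0
    age_slope: float = 0.0

    def expected_minute_value(self, vo2: float, sex: str, age: float) -> float:
        f = 1.0 if sex == "female" else 0.0
        mu = (
            self.intercept
            + self.sex_intercept_offset * f
            + (self.slope + self.sex_slope_offset * f) * vo2
            + self.age_slope * (age - _AGE_CENTER)
        )
        return max(mu, 0.0)


def _model_from_cutpoints(cut_mod: float, cut_vig: float, sd: float,
                          age_slope: float = 0.0) -> MetricModel:
    """Back-solve intercept/slope from the metric values predicted at 3
    and 6 METs (VO2 10.5 and 21.0); split noise 1:3 between subject and
    residual variance."""
    slope = (cut_vig - cut_mod) / 10.5
    return MetricModel(
        intercept=cut_mod - 10.5 * slope,
        slope=slope,
        between_sd=0.5 * sd,
        residual_sd=(np.sqrt(3.0) / 2.0) * sd,
        age_slope=age_slope,
    )


def _sexed(base: MetricModel, female: MetricModel) -> MetricModel:
    return replace(
        base,
        sex_intercept_offset=female.intercept - base.intercept,
        sex_slope_offset=female.slope - base.slope,
    )


def _default_metric_models() -> dict[tuple[str, str], MetricModel]:
    m: dict[tuple[str, str], MetricModel] = {}
    # VM counts/min; cut-points (moderate, vigorous) anchor each model
    m[("ankle_dominant", "vm_counts")] = _sexed(
        _model_from_cutpoints(8829, 12482, 3000, age_slope=-250),
        _model_from_cutpoints(9365, 20962, 3000),
    )
    m[("ankle_nondominant", "vm_counts")] = _sexed(
        _model_from_cutpoints(8636, 13242, 3400, age_slope=-250),
        _model_from_cutpoints(9460, 21683, 3400),
    )
    m[("wrist_dominant", "vm_counts")] = _model_from_cutpoints(3997, 8391, 3060)
    m[("wrist_nondominant", "vm_counts")] = _model_from_cutpoints(3268, 7890, 2630)
    m[("hip_correct", "vm_counts")] = _model_from_cutpoints(2857, 6799, 1320)
    m[("hip_erroneous", "vm_counts")] = _model_from_cutpoints(2811, 7567, 1350)
    # ENMO mg (minute-average)
    m[("ankle_dominant", "enmo_mg")] = _sexed(
        _model_from_cutpoints(323, 520, 140, age_slope=-12),
        _model_from_cutpoints(361, 866, 140),
    )
    m[("ankle_nondominant", "enmo_mg")] = _sexed(
        _model_from_cutpoints(316, 484, 140, age_slope=-12),
        _model_from_cutpoints(346, 880, 140),
    )
    m[("wrist_dominant", "enmo_mg")] = _model_from_cutpoints(122, 234, 105)
    m[("wrist_nondominant", "enmo_mg")] = _model_from_cutpoints(100, 245, 92)
    m[("hip_correct", "enmo_mg")] = _model_from_cutpoints(82, 191, 40)
    m[("hip_erroneous", "enmo_mg")] = _model_from_cutpoints(94, 230, 38)
    return m


def _default_met_anchors() -> dict[str, tuple[float, float]]:
    anchors = {st.label: (st.target_met, 0.4) for st in default_stages()
               if st.stage_type == "treadmill"}
    anchors.update({
        "reading": (0.94, 0.14),
        "cleaning": (3.0, 0.9),
        "shopping": (3.4, 0.2),
        "aerobics": (4.6, 1.0),
        "cycling": (4.7, 1.7),
    })
    return anchors


def _default_attenuation() -> dict[tuple[str, str, str], float]:
    """Movement-to-VO2 coupling per (site group, metric, activity).

    1.0 means movement tracks energy cost as on the treadmill; <1
    decouples (e.g. cycling barely moves the hip), >1 over-expresses
    (arm-heavy aerobics at the wrist). Applied to everyday stages as
    vo2_eff = rest + c * (vo2 - rest).
    """
    att: dict[tuple[str, str, str], float] = {}
    for metric in METRICS:
        for grp in ("ankle", "hip", "wrist"):
            att[(grp, metric, "shopping")] = 0.8
        att[("ankle", metric, "cleaning")] = 0.3
        att[("hip", metric, "cleaning")] = 0.3
        att[("hip", metric, "cycling")] = 0.1
        att[("wrist", metric, "cycling")] = 0.1
    att[("wrist", "vm_counts", "cleaning")] = 1.8
    att[("wrist", "enmo_mg", "cleaning")] = 1.5
    att[("ankle", "vm_counts", "cycling")] = 1.5
    att[("ankle", "enmo_mg", "cycling")] = 0.75
    att[("wrist", "vm_counts", "aerobics")] = 1.8
    att[("wrist", "enmo_mg", "aerobics")] = 1.7
    att[("ankle", "enmo_mg", "aerobics")] = 0.6
    att[("hip", "vm_counts", "aerobics")] = 0.8
    att[("hip", "enmo_mg", "aerobics")] = 0.6
    return att


#: per-site unit axis-weight vectors used to split a target VM into axes
_AXIS_WEIGHTS = {
    "hip": np.array([0.72, 0.49, 0.49]),
    "ankle": np.array([0.66, 0.55, 0.51]),
    "wrist": np.array([0.60, 0.58, 0.55]),
}

#: orientation set cycled through for still windows (covers all octants)
_STILL_ORIENTATIONS = np.array(
    [[sx, sy, sz] for sx in (1.0, -1.0) for sy in (1.0, -1.0) for sz in (1.0, -1.0)]
    + [[1.0, 0.2, 0.2], [-0.2, 1.0, -0.2], [0.2, -0.2, 1.0], [-1.0, -0.3, 0.3]]
)
_STILL_ORIENTATIONS /= np.linalg.norm(_STILL_ORIENTATIONS, axis=1, keepdims=True)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults reproduce the study design."""

    n_participants: int = 20
    sex_ratio: float = 11 / 20  # proportion male
    age_mean_sd: dict = field(default_factory=lambda: {
        "male": (63.9, 4.3), "female": (61.7, 2.1)})
    age_range: tuple[int, int] = (55, 75)
    height_mean_sd: dict = field(default_factory=lambda: {
        "male": (173.9, 4.2), "female": (161.7, 7.4)})
    mass_mean_sd: dict = field(default_factory=lambda: {
        "male": (78.6, 14.3), "female": (72.0, 16.0)})
    placements: tuple[str, ...] = PLACEMENTS
    metrics: tuple[str, ...] = METRICS
    met_anchors: dict = field(default_factory=_default_met_anchors)
    metric_models: dict = field(default_factory=_default_metric_models)
    attenuation: dict = field(default_factory=_default_attenuation)
    breath_interval_s: float = 4.0
    breath_noise_sd: float = 0.3  # ml·kg⁻¹·min⁻¹ per breath
    epoch_jitter_frac: float = 0.2  # within-minute 1-s wiggle, zero-sum
    #: fraction of residual variance shared within a placement group
    #: (limb pairs record the same movement; marginal sd is unchanged)
    residual_shared_frac: float = 0.8
    sampling_rate: float = 30.0
    sensor_noise_g: float = 0.002
    still_duration_s: float = 12.0
    offset_error_g: float = 0.05  # max per-axis miscalibration offset
    gain_error: float = 0.02  # max relative per-axis gain error
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if not self.placements:
            raise ConfigurationError("placements must be non-empty")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        for _, (_, sd) in self.met_anchors.items():
            if sd < 0:
                raise ConfigurationError("MET anchor sd must be >= 0")
        for key, mm in self.metric_models.items():
            if mm.between_sd < 0 or mm.residual_sd < 0:
                raise ConfigurationError(f"negative sd in metric model {key}")
        for p in self.placements:
            for met in self.metrics:
                if (p, met) not in self.metric_models:
                    raise ConfigurationError(f"no metric model for ({p}, {met})")

    def attenuation_for(self, placement: str, metric: str, activity: str) -> float:
        return self.attenuation.get((placement_group(placement), metric, activity), 1.0)

    def copy(self) -> "SimulationConfig":
        return copy.deepcopy(self)


@dataclass
class StageRecord:
    """One protocol stage of one session with its simulated signals."""

    stage: ProtocolStage
    counts_1s: dict  # placement -> (duration_s, 3) int array
    enmo_1s: dict  # placement -> (duration_s,) mg array
    truth: dict  # met, mean_vo2, expected metric per (placement, metric)
    dropped: bool = False

    def counts_series(self, placement: str) -> EpochSeries:
        vm = np.sqrt((self.counts_1s[placement].astype(float) ** 2).sum(axis=1))
        return EpochSeries(placement, "vm_counts", 1.0, vm, self.stage.start_s)

    def enmo_series(self, placement: str) -> EpochSeries:
        return EpochSeries(placement, "enmo_mg", 1.0, self.enmo_1s[placement],
                           self.stage.start_s)


@dataclass
class SimulatedSession:
    participant: ParticipantProfile
    stages: list[StageRecord]
    vo2: CalorimetrySeries


# ---------------------------------------------------------------- participants


def simulate_participants(config: SimulationConfig) -> list[ParticipantProfile]:
    """Draw the cohort demographics.

    Deterministic given ``config.seed``; male count is
    ``floor(n * sex_ratio)``, the remainder female. Ages are integer
    years clipped to the configured range.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_male = int(np.floor(config.n_participants * config.sex_ratio))
    sexes = ["male"] * n_male + ["female"] * (config.n_participants - n_male)
    out = []
    lo, hi = config.age_range
    for i, sex in enumerate(sexes):
        am, asd = config.age_mean_sd[sex]
        hm, hsd = config.height_mean_sd[sex]
        mm, msd = config.mass_mean_sd[sex]
        age = int(round(np.clip(rng.normal(am, asd), lo, hi)))
        height = max(rng.normal(hm, hsd), 120.0)
        mass = max(rng.normal(mm, msd), 40.0)
        side = "right" if rng.random() < 0.9 else "left"
        out.append(ParticipantProfile(f"P{i + 1:03d}", sex, age, height, mass, side))
    return out


# ------------------------------------------------------------------ VO2 series


def simulate_vo2_series(
    participant: ParticipantProfile,
    stage: ProtocolStage,
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_effect: float = 0.0,
) -> CalorimetrySeries:
    """Breath-by-breath VO2 for one stage.

    Inter-breath intervals are exponential around the configured mean
    (Poisson-like breath arrivals); each breath's VO2 is the stage mean
    (``target_met * 3.5 + participant_effect``) plus Gaussian noise,
    floored at a small positive value.
    """
    if stage.target_met is None:
        raise ValueError("stage needs a target_met for simulation")
    if stage.start_s is None:
        raise ValueError("stage needs a start time")
    mean_vo2 = stage.target_met * ML_O2_PER_MET + participant_effect
    times = []
    t = stage.start_s + rng.exponential(config.breath_interval_s)
    while t < stage.end_s:
        times.append(t)
        t += max(rng.exponential(config.breath_interval_s), 0.2)
    if not times:  # degenerate very short stage: one breath at midpoint
        times = [stage.start_s + stage.duration_s / 2.0]
    times = np.asarray(times)
    vo2 = np.maximum(mean_vo2 + rng.normal(0.0, config.breath_noise_sd, times.size), 0.05)
    return CalorimetrySeries(times, vo2, participant.id)


# ---------------------------------------------------------------- epoch metrics


def _split_counts(vm_per_s: np.ndarray, placement: str) -> np.ndarray:
    """Decompose per-second VM into non-negative integer axis counts
    using fixed site-specific weights (only VM is analysed downstream)."""
    w = _AXIS_WEIGHTS[placement_group(placement)]
    w = w / np.linalg.norm(w)
    return np.maximum(np.round(vm_per_s[:, None] * w), 0.0).astype(np.int64)


def simulate_epoch_metrics(
    participant: ParticipantProfile,
    stage: ProtocolStage,
    placement: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    stage_vo2: float,
    between_effects: dict | None = None,
    shared_minute_noise: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-second axis counts and ENMO for one stage and placement.

    Minute-level values are drawn around the linear model expectation
    (with any between-subject effect), then spread across the sixty
    seconds with zero-sum jitter so minute aggregates are exact. When
    ``shared_minute_noise`` supplies standard-normal draws per
    (site group, metric), the configured fraction of residual variance
    is taken from them, correlating placements that record the same
    movement; the marginal residual sd is unchanged. Returns
    ``(counts_1s, enmo_1s, expected)`` where ``expected`` maps metric ->
    noiseless expected minute value.
    """
    if placement not in config.placements:
        raise LookupError(f"unknown placement {placement!r}")
    n_sec = int(round(stage.duration_s))
    n_min = max(n_sec // 60, 1)
    expected: dict[str, float] = {}
    per_metric: dict[str, np.ndarray] = {}
    for metric in config.metrics:
        mm: MetricModel = config.metric_models[(placement, metric)]
        c = (config.attenuation_for(placement, metric, stage.label)
             if stage.stage_type == "everyday" else 1.0)
        vo2_eff = RESTING_VO2 + c * (stage_vo2 - RESTING_VO2)
        mu = mm.expected_minute_value(vo2_eff, participant.sex, participant.age)
        be = between_effects or {}
        b = be.get((placement, metric),
                   be.get((placement_group(placement), metric), 0.0))
        mu = max(mu + b, 0.0)
        expected[metric] = mu
        own = rng.normal(0.0, 1.0, n_min)
        shared = (shared_minute_noise or {}).get(
            (placement_group(placement), metric))
        if shared is not None:
            f = config.residual_shared_frac
            noise = np.sqrt(f) * shared[:n_min] + np.sqrt(1.0 - f) * own
        else:
            noise = own
        minute_vals = np.maximum(mu + mm.residual_sd * noise, 0.0)
        sec = np.empty(n_min * 60)
        for k, v in enumerate(minute_vals):
            base = v / 60.0 if metric == "vm_counts" else v
            jit = rng.normal(0.0, config.epoch_jitter_frac * base, 60)
            jit -= jit.mean()  # zero-sum: minute aggregate stays exact
            sec[k * 60 : (k + 1) * 60] = np.maximum(base + jit, 0.0)
        per_metric[metric] = sec[:n_sec]
    counts = (_split_counts(per_metric["vm_counts"], placement)
              if "vm_counts" in per_metric else None)
    return counts, per_metric.get("enmo_mg"), expected


# ------------------------------------------------------------------ raw signal


def draw_miscalibration(config: SimulationConfig,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """True per-axis (gain, offset) distortion applied to a raw signal."""
    gain = rng.uniform(1.0 - config.gain_error, 1.0 + config.gain_error, 3)
    offset = rng.uniform(-config.offset_error_g, config.offset_error_g, 3)
    return gain, offset


def simulate_raw_signal(
    participant: ParticipantProfile,
    stage: ProtocolStage,
    placement: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    true_enmo_mg: float,
    miscalibration: tuple[np.ndarray, np.ndarray] | None = None,
) -> RawTriaxialSignal:
    """30 Hz tri-axial signal for one stage with a known true ENMO.

    The movement part is a unit gravity vector scaled by
    ``1 + e(t)`` with ``e(t) = enmo * (1 - cos(2*pi*f*t))`` (rectified
    magnitude averaging exactly to the target ENMO); a still window of
    the configured duration precedes the stage for calibration use.
    Optional miscalibration maps the signal through
    ``gain * true + offset`` per axis; small sensor noise is added.
    """
    rate = config.sampling_rate
    n_still = int(round(config.still_duration_s * rate))
    n_move = int(round(stage.duration_s * rate))
    u_still = _STILL_ORIENTATIONS[rng.integers(len(_STILL_ORIENTATIONS))]
    u_move = rng.normal(size=3)
    u_move /= np.linalg.norm(u_move)
    t = np.arange(n_move) / rate
    e = (true_enmo_mg / 1000.0) * (1.0 - np.cos(2.0 * np.pi * 1.5 * t))
    move = (1.0 + e)[:, None] * u_move
    still = np.tile(u_still, (n_still, 1))
    samples = np.vstack([still, move])
    if miscalibration is not None:
        gain, offset = miscalibration
        samples = samples * gain + offset
    samples = samples + rng.normal(0.0, config.sensor_noise_g, samples.shape)
    start = (stage.start_s or 0.0) - config.still_duration_s
    return RawTriaxialSignal(placement, rate, samples, start)


def simulate_calibration_session(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_still_windows: int = 12,
    movement_gap_s: float = 8.0,
) -> tuple[RawTriaxialSignal, np.ndarray, np.ndarray]:
    """A miscalibrated signal with orientation-diverse still windows.

    Alternates still windows (cycling through an octant-covering
    orientation set) with short movement bursts, then distorts the whole
    signal by a drawn per-axis gain/offset. The default 12 s + 8 s
    layout keeps still windows aligned with the detector's 10-s blocks.
    Returns ``(signal, true_gain, true_offset)``.
    """
    rate = config.sampling_rate
    n_still = int(round(config.still_duration_s * rate))
    n_gap = int(round(movement_gap_s * rate))
    chunks = []
    for k in range(n_still_windows):
        u = _STILL_ORIENTATIONS[k % len(_STILL_ORIENTATIONS)]
        chunks.append(np.tile(u, (n_still, 1)))
        t = np.arange(n_gap) / rate
        osc = 0.3 * np.sin(2.0 * np.pi * 2.0 * t)
        direc = rng.normal(size=3)
        direc /= np.linalg.norm(direc)
        chunks.append((1.0 + osc)[:, None] * direc)
    true_signal = np.vstack(chunks)
    gain, offset = draw_miscalibration(config, rng)
    observed = true_signal * gain + offset
    observed += rng.normal(0.0, config.sensor_noise_g, observed.shape)
    return RawTriaxialSignal("calibration", rate, observed), gain, offset


# -------------------------------------------------------------------- sessions


def simulate_session(
    participant: ParticipantProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedSession:
    """Full session for one participant: stages, VO2, epoch metrics, truth.

    A single standard-normal fitness effect per participant shifts the
    MET of every stage by ``z * anchor_sd`` (shared across activities,
    giving the between-placement correlation real cohorts show); a
    per-(site group, metric) random intercept with the configured
    between-subject sd shifts the accelerometer metrics.
    """
    z = rng.normal()
    # one movement-style effect per site group x metric: both wrists (or
    # ankles, or hip positions) of a person share it
    between: dict[tuple[str, str], float] = {}
    for (placement, metric), mm in config.metric_models.items():
        key = (placement_group(placement), metric)
        if key not in between:
            between[key] = rng.normal(0.0, mm.between_sd)
    stages_out: list[StageRecord] = []
    all_times: list[np.ndarray] = []
    all_vo2: list[np.ndarray] = []
    for proto in default_stages():
        _, anchor_sd = config.met_anchors[proto.label]
        anchor_mean, _ = config.met_anchors[proto.label]
        stage = replace(proto, target_met=anchor_mean)
        met_true = max(anchor_mean + z * anchor_sd, 0.3)
        effect = (met_true - anchor_mean) * ML_O2_PER_MET
        series = simulate_vo2_series(participant, stage, config, rng, effect)
        all_times.append(series.times)
        all_vo2.append(series.vo2)
        vo2_true = met_true * ML_O2_PER_MET
        counts: dict[str, np.ndarray] = {}
        enmo: dict[str, np.ndarray] = {}
        expected: dict[tuple[str, str], float] = {}
        dropped = bool(config.missing_rate and rng.random() < config.missing_rate)
        if not dropped:
            n_min = max(int(round(stage.duration_s)) // 60, 1)
            shared = {
                (placement_group(p), metric): rng.normal(0.0, 1.0, n_min)
                for p in config.placements for metric in config.metrics
            }
            for placement in config.placements:
                c, e, exp = simulate_epoch_metrics(
                    participant, stage, placement, config, rng,
                    stage_vo2=vo2_true, between_effects=between,
                    shared_minute_noise=shared,
                )
                if c is not None:
                    counts[placement] = c
                if e is not None:
                    enmo[placement] = e
                for metric, v in exp.items():
                    expected[(placement, metric)] = v
        truth = {
            "met": met_true,
            "mean_vo2": vo2_true,
            "expected_metric": expected,
        }
        stages_out.append(StageRecord(stage, counts, enmo, truth, dropped))
    vo2_series = CalorimetrySeries(
        np.concatenate(all_times), np.concatenate(all_vo2), participant.id
    )
    return SimulatedSession(participant, stages_out, vo2_series)


def simulate_cohort(config: SimulationConfig) -> list[SimulatedSession]:
    """Simulate every participant's session; deterministic given the seed."""
    participants = simulate_participants(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    return [simulate_session(p, config, rng) for p in participants]
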