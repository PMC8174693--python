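"""Cut-point validation: confusion proportions, Pearson r, ICC(3,1).

Everyday-activity observations are classified with the derived
cut-points and compared with the calorimetry reference intensity. The
headline agreement statistic is the single-measures intraclass
correlation of a two-way model under absolute agreement (the McGraw &
Wong A,1 form, labelled ICC(3,1) in this literature), computed on
intensity classes coded ordinally 1/2/3.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cutpoints import CutpointModel
from .protocol import INTENSITY_CODES, INTENSITY_LEVELS

__all__ = [
    "classify_by_cutpoints",
    "select_model",
    "classify_observations",
    "confusion_proportions",
    "pearson_r",
    "icc_two_way_mixed_absolute_single",
    "ValidationReport",
    "build_validation_report",
    "UndefinedCorrelationError",
]

_PLACEMENT_PAIRS = {
    "wrist": ("wrist_dominant", "wrist_nondominant"),
    "ankle": ("ankle_dominant", "ankle_nondominant"),
    "hip": ("hip_correct", "hip_erroneous"),
}


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant input or too few points)."""


def classify_by_cutpoints(metric_value: float, model: CutpointModel) -> str:
    """Intensity class for a per-minute metric value.

    Half-open bins mirroring the MET rule: values below the moderate
    cut-point are sedentary/light, values at or above the vigorous
    cut-point are vigorous.
    """
    if model.cut_moderate > model.cut_vigorous:
        raise ValueError(
            f"{model.placement}/{model.metric}: cut-points out of order"
        )
    if metric_value < model.cut_moderate:
        return "sedentary_light"
    if metric_value < model.cut_vigorous:
        return "moderate"
    return "vigorous"


def select_model(
    models: list[CutpointModel], placement: str, metric: str, sex: str
) -> CutpointModel:
    """Pick the model for a placement/metric; the participant's sex
    selects the stratum when the group was sex-stratified."""
    candidates = [m for m in models if m.placement == placement and m.metric == metric]
    for m in candidates:
        if m.stratum == "all":
            return m
    for m in candidates:
        if m.stratum == sex:
            return m
    raise LookupError(f"no cut-point model for {placement}/{metric} (sex={sex})")


def classify_observations(
    dataset: pd.DataFrame, models: list[CutpointModel]
) -> pd.DataFrame:
    """Classify everyday-activity rows of a long dataset.

    Expects columns participant, sex, activity (or stage), placement,
    metric, metric_value, vo2, reference_intensity. Returns the frame
    with a ``predicted_intensity`` column appended.
    """
    df = dataset.copy()
    if "activity" not in df.columns:
        df = df.rename(columns={"stage": "activity"})
    skipped: set[tuple[str, str]] = set()
    preds = []
    for row in df.itertuples():
        model = select_model(models, row.placement, row.metric, row.sex)
        if model.cut_moderate > model.cut_vigorous:  # negative-slope fit
            skipped.add((row.placement, row.metric))
            preds.append(None)
            continue
        preds.append(classify_by_cutpoints(row.metric_value, model))
    if skipped:
        warnings.warn(
            "unordered cut-points (negative slope), observations skipped for: "
            + ", ".join("/".join(k) for k in sorted(skipped)),
            stacklevel=2,
        )
    df["predicted_intensity"] = preds
    return df[df["predicted_intensity"].notna()].copy()


def _triple(classes: pd.Series) -> dict[str, float]:
    n = len(classes)
    return {
        f"pct_{lvl}": 100.0 * float((classes == lvl).sum()) / n
        for lvl in INTENSITY_LEVELS
    }


def confusion_proportions(classified: pd.DataFrame) -> pd.DataFrame:
    """Percent of observations per intensity class, by activity and source.

    One row per activity (plus ``overall``) and source, where source is
    ``reference`` or ``placement|metric``. Exact percentages are kept;
    round only for display.
    """
    rows = []
    activities = list(classified["activity"].unique()) + ["overall"]
    for act in activities:
        sub = classified if act == "overall" else classified[classified["activity"] == act]
        if sub.empty:
            continue
        ref = sub.drop_duplicates(["participant", "activity"])
        rows.append({"activity": act, "source": "reference",
                     **_triple(ref["reference_intensity"])})
        for (placement, metric), g in sub.groupby(["placement", "metric"], sort=True):
            rows.append({"activity": act, "source": f"{placement}|{metric}",
                         **_triple(g["predicted_intensity"])})
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Product-moment correlation with explicit degeneracy errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def icc_two_way_mixed_absolute_single(ratings) -> float:
    """Single-measures ICC, two-way model, absolute agreement.

    ``ratings`` is an (n_subjects, k_raters) table; rows containing
    missing cells are dropped listwise. From the two-way ANOVA mean
    squares (subjects MSR, raters MSC, residual MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Identical columns give exactly 1.0.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D table")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return 1.0 if ss_total == 0.0 else 0.0
    return float((msr - mse) / denom)


def _icc_device_vs_reference(sub: pd.DataFrame) -> float:
    table = np.column_stack([
        sub["predicted_intensity"].map(INTENSITY_CODES).to_numpy(float),
        sub["reference_intensity"].map(INTENSITY_CODES).to_numpy(float),
    ])
    return icc_two_way_mixed_absolute_single(table)


@dataclass
class ValidationReport:
    """All robustness statistics for the everyday-activity part."""

    proportions: pd.DataFrame
    icc_vs_reference: dict = field(default_factory=dict)
    icc_vs_reference_without_cycling: dict = field(default_factory=dict)
    icc_vm_vs_enmo: dict = field(default_factory=dict)
    pearson_vs_vo2: dict = field(default_factory=dict)
    paired_placement_r: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def keyed(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v
                    for k, v in d.items()}

        return {
            "proportions": self.proportions.to_dict(orient="records"),
            "icc_vs_reference": keyed(self.icc_vs_reference),
            "icc_vs_reference_without_cycling": keyed(
                self.icc_vs_reference_without_cycling),
            "icc_vm_vs_enmo": keyed(self.icc_vm_vs_enmo),
            "pearson_vs_vo2": keyed(self.pearson_vs_vo2),
            "paired_placement_r": keyed(self.paired_placement_r),
        }


def build_validation_report(classified: pd.DataFrame) -> ValidationReport:
    """Assemble the full validation report from classified observations.

    Computes confusion proportions per activity, device-vs-reference
    ICCs per placement x metric (with and without cycling), VM-vs-ENMO
    ICCs per placement, Pearson r of metric vs VO2 per activity, and
    correlations between paired placements (dominant vs non-dominant,
    correct vs erroneous hip).
    """
    required = {"participant", "activity", "placement", "metric",
                "metric_value", "vo2", "predicted_intensity",
                "reference_intensity"}
    missing = required - set(classified.columns)
    if missing:
        raise ValueError(f"classified table missing columns {sorted(missing)}")

    report = ValidationReport(proportions=confusion_proportions(classified))
    no_cyc = classified[classified["activity"] != "cycling"]
    for (placement, metric), g in classified.groupby(["placement", "metric"]):
        report.icc_vs_reference[(placement, metric)] = _icc_device_vs_reference(g)
        g2 = no_cyc[(no_cyc["placement"] == placement) & (no_cyc["metric"] == metric)]
        if len(g2) >= 2:
            report.icc_vs_reference_without_cycling[(placement, metric)] = (
                _icc_device_vs_reference(g2)
            )
        for act, ga in g.groupby("activity"):
            try:
                r = pearson_r(ga["metric_value"], ga["vo2"])
            except UndefinedCorrelationError:
                r = float("nan")
            report.pearson_vs_vo2[(placement, metric, act)] = r

    # VM vs ENMO agreement of ordinal classifications, per placement
    wide = classified.pivot_table(
        index=["participant", "activity", "placement"],
        columns="metric",
        values="predicted_intensity",
        aggfunc="first",
    )
    if {"vm_counts", "enmo_mg"} <= set(wide.columns):
        for placement, g in wide.groupby(level="placement"):
            pair = g.dropna()
            if len(pair) >= 2:
                table = np.column_stack([
                    pair["vm_counts"].map(INTENSITY_CODES).to_numpy(float),
                    pair["enmo_mg"].map(INTENSITY_CODES).to_numpy(float),
                ])
                report.icc_vm_vs_enmo[placement] = (
                    icc_two_way_mixed_absolute_single(table)
                )

    # paired placements: metric values correlated across participant x activity
    values = classified.pivot_table(
        index=["participant", "activity"], columns=["placement", "metric"],
        values="metric_value", aggfunc="first",
    )
    for pair_name, (a, b) in _PLACEMENT_PAIRS.items():
        for metric in classified["metric"].unique():
            if (a, metric) in values.columns and (b, metric) in values.columns:
                sub = values[[(a, metric), (b, metric)]].dropna()
                if len(sub) >= 3:
                    try:
                        report.paired_placement_r[(pair_name, metric)] = pearson_r(
                            sub[(a, metric)], sub[(b, metric)]
                        )
                    except UndefinedCorrelationError:
                        pass
    return report
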