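"""Cut-point derivation: OLS of metric on VO2, residual confounding, strata.

For each placement x metric, per-minute metric values from the treadmill
stages are regressed on stage VO2 (ordinary least squares, pooling all
single observations). Cut-points are the predicted metric values at
3 METs (VO2 = 10.5) and 6 METs (VO2 = 21.0). Confounding by sex and age
is tested by regressing the residuals jointly on both at alpha = 0.05;
a significant sex term triggers sex-stratified refits (age never does:
age-specific cut-points are not a deliverable of this design).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metabolic import ML_O2_PER_MET

__all__ = [
    "CalibrationObservation",
    "CutpointModel",
    "ConfoundingReport",
    "SingularFitError",
    "StratumSizeError",
    "fit_metric_on_vo2",
    "predict_cutpoints",
    "test_residual_confounding",
    "derive_cutpoints",
    "cutpoints_to_frame",
]

VO2_MODERATE = 3.0 * ML_O2_PER_MET  # 10.5
VO2_VIGOROUS = 6.0 * ML_O2_PER_MET  # 21.0


class SingularFitError(ValueError):
    """Design matrix degenerate (e.g. constant VO2)."""


class StratumSizeError(ValueError):
    """A stratum has too few observations to fit."""


@dataclass
class CalibrationObservation:
    participant: str
    sex: str
    age: float
    placement: str
    metric: str
    stage: str
    metric_value: float
    vo2: float

    @property
    def met(self) -> float:
        return self.vo2 / ML_O2_PER_MET


@dataclass
class CutpointModel:
    placement: str
    metric: str
    stratum: str  # "all" | "male" | "female"
    intercept: float
    slope: float
    cut_moderate: float
    cut_vigorous: float
    r_squared: float
    n_obs: int


@dataclass
class ConfoundingReport:
    placement: str
    metric: str
    p_sex: float | None
    p_age: float | None
    stratify_by_sex: bool
    alpha: float = 0.05


def fit_metric_on_vo2(vo2, metric_value):
    """OLS with intercept of metric on VO2.

    Returns ``(intercept, slope, r_squared, residuals)``; residuals in
    input order. Requires >= 3 observations with >= 2 distinct VO2
    values.
    """
    x = np.asarray(vo2, dtype=float)
    y = np.asarray(metric_value, dtype=float)
    if x.size < 3:
        raise SingularFitError("need at least 3 observations")
    if np.unique(x).size < 2:
        raise SingularFitError("VO2 is constant; slope is unidentified")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(res.rsquared) if np.var(y) > 0 else 0.0
    return (
        float(res.params[0]),
        float(res.params[1]),
        r2,
        np.asarray(res.resid),
    )


def predict_cutpoints(intercept: float, slope: float) -> tuple[float, float]:
    """Predicted metric at 3 METs (moderate) and 6 METs (vigorous)."""
    cut_mod = intercept + slope * VO2_MODERATE
    cut_vig = intercept + slope * VO2_VIGOROUS
    if cut_vig < cut_mod:
        warnings.warn(
            "negative slope: vigorous cut-point below moderate cut-point",
            stacklevel=2,
        )
    return cut_mod, cut_vig


def test_residual_confounding(
    residuals, sex, age, alpha: float = 0.05,
    placement: str = "", metric: str = "",
) -> ConfoundingReport:
    """Joint OLS of first-stage residuals on sex (0/1, female=1) and age.

    Two-sided t-test p-values per coefficient; sex below ``alpha``
    triggers stratification. A single-sex sample leaves the sex term
    unidentified: p_sex is reported as None and no stratification occurs.
    """
    r = np.asarray(residuals, dtype=float)
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    if not (r.size == sex.size == age.size):
        raise ValueError("residuals, sex and age must have equal length")
    sex01 = np.where(sex == "female", 1.0, 0.0) if sex.dtype.kind in "UO" \
        else sex.astype(float)
    if np.unique(sex01).size < 2:
        return ConfoundingReport(placement, metric, None,
                                 _age_only_p(r, age), False, alpha)
    X = sm.add_constant(np.column_stack([sex01, age]))
    res = sm.OLS(r, X).fit()
    p_sex, p_age = float(res.pvalues[1]), float(res.pvalues[2])
    return ConfoundingReport(placement, metric, p_sex, p_age,
                             bool(p_sex < alpha), alpha)


def _age_only_p(residuals: np.ndarray, age: np.ndarray) -> float | None:
    if np.unique(age).size < 2:
        return None
    res = sm.OLS(residuals, sm.add_constant(age)).fit()
    return float(res.pvalues[1])


def _fit_group(g: pd.DataFrame, placement: str, metric: str,
               stratum: str) -> CutpointModel:
    if len(g) < 3:
        raise StratumSizeError(
            f"{placement}/{metric} stratum {stratum!r}: "
            f"only {len(g)} observations (need >= 3)"
        )
    intercept, slope, r2, _ = fit_metric_on_vo2(g["vo2"], g["metric_value"])
    cut_mod, cut_vig = predict_cutpoints(intercept, slope)
    return CutpointModel(placement, metric, stratum, intercept, slope,
                         cut_mod, cut_vig, r2, len(g))


def derive_cutpoints(
    observations: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[CutpointModel], list[ConfoundingReport]]:
    """Derive cut-points per placement x metric with confounding checks.

    ``observations`` is a long table with columns participant, sex, age,
    placement, metric, stage, metric_value, vo2 (treadmill stages only).
    Rows with missing metric or VO2 are dropped listwise per group. For
    every group, a pooled fit is run first; if the residual sex test is
    significant at ``alpha``, separate male/female models are returned,
    otherwise a single ``all`` model.
    """
    required = {"participant", "sex", "age", "placement", "metric",
                "metric_value", "vo2"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns {sorted(missing)}")
    obs = observations.dropna(subset=["metric_value", "vo2"])
    models: list[CutpointModel] = []
    reports: list[ConfoundingReport] = []
    for (placement, metric), g in obs.groupby(["placement", "metric"], sort=True):
        if g.empty:
            continue
        intercept, slope, r2, resid = fit_metric_on_vo2(g["vo2"], g["metric_value"])
        report = test_residual_confounding(
            resid, g["sex"].to_numpy(), g["age"].to_numpy(), alpha,
            placement=placement, metric=metric,
        )
        reports.append(report)
        if report.stratify_by_sex:
            for stratum in ("male", "female"):
                models.append(_fit_group(g[g["sex"] == stratum],
                                         placement, metric, stratum))
        else:
            cut_mod, cut_vig = predict_cutpoints(intercept, slope)
            models.append(CutpointModel(placement, metric, "all", intercept,
                                        slope, cut_mod, cut_vig, r2, len(g)))
    return models, reports


def cutpoints_to_frame(models: list[CutpointModel]) -> pd.DataFrame:
    """Cut-point table shaped like the published ones (one row per
    placement/stratum/metric)."""
    return pd.DataFrame(
        [
            {
                "placement": m.placement,
                "metric": m.metric,
                "stratum": m.stratum,
                "intercept": m.intercept,
                "slope": m.slope,
                "cut_moderate": m.cut_moderate,
                "cut_vigorous": m.cut_vigorous,
                "r_squared": m.r_squared,
                "n_obs": m.n_obs,
            }
            for m in models
        ]
    )
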