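"""Validation statistics: classification, confusion tables, Pearson, ICC."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from acticut.agreement import (
    UndefinedCorrelationError,
    build_validation_report,
    classify_by_cutpoints,
    classify_observations,
    confusion_proportions,
    icc_two_way_mixed_absolute_single,
    pearson_r,
    select_model,
)
from acticut.cohort import SimulationConfig, simulate_cohort
from acticut.cutpoints import CutpointModel, derive_cutpoints
from acticut.metabolic import classify_intensity
from acticut.pipeline import build_study_dataset, melt_metrics

HIP_VM = CutpointModel("hip_correct", "vm_counts", "all", -1085.0, 375.43,
                       2857.0, 6799.0, 0.37, 100)


class TestClassification:
    @pytest.mark.parametrize("value,expected", [
        (2856.0, "sedentary_light"),
        (2857.0, "moderate"),
        (6798.9, "moderate"),
        (6799.0, "vigorous"),
        (1e6, "vigorous"),
    ])
    def test_boundaries_mirror_met_rule(self, value, expected):
        assert classify_by_cutpoints(value, HIP_VM) == expected

    def test_unordered_cutpoints_rejected(self):
        bad = CutpointModel("hip_correct", "vm_counts", "all", 0, -10,
                            5000.0, 4000.0, 0.1, 10)
        with pytest.raises(ValueError, match="out of order"):
            classify_by_cutpoints(100.0, bad)

    def test_sex_selects_stratified_model(self):
        male = CutpointModel("ankle_dominant", "vm_counts", "male",
                             5176.0, 347.9, 8829.0, 12482.0, 0.08, 55)
        female = CutpointModel("ankle_dominant", "vm_counts", "female",
                               -2232.0, 1104.5, 9365.0, 20962.0, 0.51, 45)
        models = [male, female]
        assert select_model(models, "ankle_dominant", "vm_counts", "female") is female
        assert select_model(models, "ankle_dominant", "vm_counts", "male") is male
        with pytest.raises(LookupError):
            select_model(models, "hip_correct", "vm_counts", "male")


class TestConfusionProportions:
    def _frame(self, predicted, reference, activity="reading"):
        n = len(predicted)
        return pd.DataFrame({
            "participant": [f"P{i}" for i in range(n)],
            "activity": activity,
            "placement": "hip_correct",
            "metric": "vm_counts",
            "metric_value": 100.0,
            "vo2": 3.3,
            "predicted_intensity": predicted,
            "reference_intensity": reference,
        })

    def test_all_sedentary_reading_row(self):
        df = self._frame(["sedentary_light"] * 20, ["sedentary_light"] * 20)
        out = confusion_proportions(df)
        ref = out[(out.activity == "reading") & (out.source == "reference")]
        assert ref.iloc[0]["pct_sedentary_light"] == 100.0
        assert ref.iloc[0]["pct_moderate"] == 0.0

    def test_perfect_agreement_rows_identical(self):
        classes = ["sedentary_light"] * 10 + ["moderate"] * 7 + ["vigorous"] * 3
        out = confusion_proportions(self._frame(classes, classes))
        ref = out[out.source == "reference"].iloc[0]
        dev = out[out.source != "reference"].iloc[0]
        for col in ("pct_sedentary_light", "pct_moderate", "pct_vigorous"):
            assert ref[col] == dev[col]

    def test_rows_sum_to_100(self, cohort_dataset):
        _, ds = cohort_dataset
        tread = ds[ds.stage_type == "treadmill"]
        models, _ = derive_cutpoints(melt_metrics(tread))
        everyday = ds[ds.stage_type == "everyday"].copy()
        everyday["reference_intensity"] = everyday["met"].map(classify_intensity)
        classified = classify_observations(melt_metrics(everyday), models)
        out = confusion_proportions(classified)
        sums = out[["pct_sedentary_light", "pct_moderate", "pct_vigorous"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestPearson:
    def test_affine_transform(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        expect = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std(ddof=0) * y.std(ddof=0)))
        assert pearson_r(x, y) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestIcc:
    def test_identical_columns_give_exactly_one(self):
        x = np.tile(np.arange(1.0, 21.0)[:, None], (1, 2))
        assert icc_two_way_mixed_absolute_single(x) == 1.0

    def test_constant_shift_penalised_despite_pearson_one(self):
        a = np.arange(1.0, 101.0)
        table = np.column_stack([a, a + 50.0])
        icc = icc_two_way_mixed_absolute_single(table)
        assert pearson_r(a, a + 50.0) == pytest.approx(1.0)
        assert icc < 0.9

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            table = rng.integers(1, 4, size=(20, 2)).astype(float)
            if np.ptp(table) == 0:
                continue
            ours = icc_two_way_mixed_absolute_single(table)
            n, k = table.shape
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": table.ravel(),
            })
            ref = pingouin.intraclass_corr(long, targets="subject",
                                           raters="rater", ratings="score")
            icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
            assert ours == pytest.approx(icc2, abs=1e-8)

    def test_insufficient_table_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way_mixed_absolute_single(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_two_way_mixed_absolute_single(np.ones((5, 1)))

    @given(arrays(np.float64, (8, 2), elements=st.floats(-100, 100)))
    @settings(max_examples=100, deadline=None)
    def test_bounded(self, table):
        # the absolute-agreement single-measures estimator is <= 1 always
        # and >= -n(k-1)/(n(k-1)-k) at finite n (here n=8, k=2: -4/3)
        icc = icc_two_way_mixed_absolute_single(table)
        n, k = table.shape
        lower = -n * (k - 1) / (n * (k - 1) - k)
        assert lower - 1e-9 <= icc <= 1.0 + 1e-9


@pytest.fixture(scope="module")
def classified():
    cfg = SimulationConfig(seed=31)
    ds = build_study_dataset(simulate_cohort(cfg))
    tread = ds[ds.stage_type == "treadmill"]
    models, _ = derive_cutpoints(melt_metrics(tread))
    everyday = ds[ds.stage_type == "everyday"].copy()
    everyday["reference_intensity"] = everyday["met"].map(classify_intensity)
    return classify_observations(melt_metrics(everyday), models)


class TestValidationReport:
    def test_perfect_agreement_scores_one(self):
        df = pd.DataFrame({
            "participant": [f"P{i}" for i in range(20)] * 2,
            "activity": ["cleaning"] * 20 + ["aerobics"] * 20,
            "placement": "hip_correct",
            "metric": "vm_counts",
            "metric_value": np.linspace(100, 8000, 40),
            "vo2": np.linspace(5, 20, 40),
        })
        df["predicted_intensity"] = ["sedentary_light"] * 20 + ["moderate"] * 20
        df["reference_intensity"] = df["predicted_intensity"]
        rep = build_validation_report(df)
        assert rep.icc_vs_reference[("hip_correct", "vm_counts")] == 1.0

    def test_cycling_exclusion_helps_hip(self, classified):
        # hip moves little on an ergometer although VO2 is high, so the
        # device-vs-reference ICC must improve once cycling is excluded
        rep = build_validation_report(classified)
        key = ("hip_correct", "vm_counts")
        assert (rep.icc_vs_reference_without_cycling[key]
                > rep.icc_vs_reference[key])

    def test_paired_placements_strongly_correlated(self, classified):
        rep = build_validation_report(classified)
        for pair in ("wrist", "ankle", "hip"):
            assert rep.paired_placement_r[(pair, "vm_counts")] > 0.9

    def test_statistics_bounded_and_keyed(self, classified):
        rep = build_validation_report(classified)
        for d in (rep.icc_vs_reference, rep.icc_vs_reference_without_cycling,
                  rep.icc_vm_vs_enmo):
            assert d, "statistic dict should not be empty"
            assert all(-1.0 <= v <= 1.0 for v in d.values())
        payload = rep.to_dict()
        assert "proportions" in payload and payload["icc_vs_reference"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            build_validation_report(pd.DataFrame({"participant": []}))
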