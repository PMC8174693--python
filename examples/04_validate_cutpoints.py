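"""Validate derived cut-points against staged everyday activities.

Applies treadmill-derived cut-points to reading, cleaning, shopping,
cycling and aerobics, then compares device-predicted intensity classes
with the calorimetry reference: confusion proportions per activity,
device-vs-reference ICC (two-way, absolute agreement, single measures)
with and without cycling, and the VM-vs-ENMO agreement per placement.
Expect cycling to wreck hip/wrist agreement (the ergometer barely moves
the trunk while VO2 is high) and the cycling-excluded ICC to improve.
"""
from acticut import SimulationConfig, build_validation_report, derive_cutpoints
from acticut.agreement import classify_observations
from acticut.cohort import simulate_cohort
from acticut.metabolic import classify_intensity
from acticut.pipeline import build_study_dataset, melt_metrics

config = SimulationConfig(seed=4)
dataset = build_study_dataset(simulate_cohort(config))
models, _ = derive_cutpoints(melt_metrics(dataset[dataset.stage_type == "treadmill"]))

everyday = dataset[dataset.stage_type == "everyday"].copy()
everyday["reference_intensity"] = everyday["met"].map(classify_intensity)
classified = classify_observations(melt_metrics(everyday), models)
report = build_validation_report(classified)

print("confusion proportions (% sedentary/light - moderate - vigorous):")
show = ["reference", "hip_correct|vm_counts", "wrist_nondominant|vm_counts"]
for act in ["reading", "cleaning", "shopping", "cycling", "aerobics", "overall"]:
    parts = []
    for src in show:
        row = report.proportions.query("activity == @act and source == @src")
        r = row.iloc[0]
        parts.append(f"{r.pct_sedentary_light:3.0f}-{r.pct_moderate:3.0f}"
                     f"-{r.pct_vigorous:3.0f}")
    print(f"  {act:9s} ref {parts[0]}   hip VM {parts[1]}   wrist VM {parts[2]}")

print("\nICC vs reference (all / without cycling):")
for key, icc in sorted(report.icc_vs_reference.items()):
    no_cyc = report.icc_vs_reference_without_cycling.get(key, float("nan"))
    print(f"  {key[0]:18s} {key[1]:9s} {icc:5.2f} / {no_cyc:5.2f}")

print("\nICC VM vs ENMO per placement:")
for placement, icc in sorted(report.icc_vm_vs_enmo.items()):
    print(f"  {placement:18s} {icc:5.2f}")
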