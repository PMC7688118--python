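"""Simulate a two-contingent cohort and recover it by DTW k-medoids.

Generates the default synthetic study (30 lower-reach + 30 upper-reach
fish), preprocesses year-1 detections into padded daily phenologies,
clusters them with k = 2, and compares the recovered labels with the
generator's ground truth.
"""

import pandas as pd

from runcontingent import PipelineConfig, SyntheticConfig, run_pipeline, simulate_cohort

dataset = simulate_cohort(SyntheticConfig(seed=42))
report = run_pipeline(
    PipelineConfig(),
    dataset.detections,
    dataset.receivers,
    dataset.fish,
    dataset.environment,
)

year1 = report.assignments.query("year == 2017").set_index("tag_id")["cluster"]
truth = dataset.truth.set_index("tag_id")["contingent_y1"]
agree = (year1 == truth.loc[year1.index]).mean()

print(report.log_lines[0])
print(f"cluster sizes: {year1.value_counts().to_dict()}")
print(f"agreement with simulated truth: {100 * agree:.1f}%")
print()
print("Each fish is labelled by its nearest medoid phenology; with the")
print("default 90-100 km vs 160-200 km reach separation the contingents")
print("are recovered essentially perfectly.")
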