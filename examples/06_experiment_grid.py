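"""Run a slice of the 120-configuration study grid and render a report.

The full default grid crosses 4 coding designs with 30 learner
configurations; here a single design runs against the non-k-NN families
so the example finishes in seconds.  Unevaluable configurations (e.g. a
singular covariance) are reported as skips, not crashes.
"""

from colonyqc import ExperimentGrid, SyntheticFeatureConfig, enumerate_grid, generate_feature_table, run_grid
from colonyqc.experiment import render_text

print("default grid size:", len(enumerate_grid()), "configurations")

table = generate_feature_table(SyntheticFeatureConfig(
    class_counts={"bad": 8, "good": 14, "semigood": 11},
    separation=4.0, seed=1,
))
grid = ExperimentGrid(designs=("ova",), knn_distances=())
results = run_grid(table, grid)
print(render_text(results))
print("rows mirror the study's result tables: per-class 'TP (TPR%)' and ACC")
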