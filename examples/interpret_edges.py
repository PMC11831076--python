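"""Which connections carry the prediction?

Primal RVR weights from the LOOCV fold models are averaged, the top 1% of
edges by mean absolute weight (40 of 4005) are selected, and the selection
is characterized by network-module pair and anatomical distance
(long-range = centroid Euclidean distance > 75 mm).
"""

import numpy as np

from memconn.interpretation import aggregate_weights, module_pair_summary, select_top_edges
from memconn.prediction import loocv_predict
from memconn.synthetic import SimulationConfig, generate_atlas, simulate_cohort

atlas = generate_atlas(90, 8, seed=1)
dmn_limbic = [i for i, m in enumerate(atlas.modules) if m in ("default mode", "limbic")]
rng = np.random.default_rng(0)
edges = set()
while len(edges) < 40:
    i, j = rng.choice(dmn_limbic, 2, replace=False)
    edges.add((min(i, j), max(i, j)))
edges = tuple(sorted(edges))

cohort = simulate_cohort(
    SimulationConfig(n_subjects=100, signal_edges=edges, random_seed=11), atlas=atlas
)
cv = loocv_predict(cohort.features(), cohort.subject_table["avlt_dr"].to_numpy())
print(f"LOOCV r = {cv.r:.3f}")

mean_w, mean_abs_w = aggregate_weights(cv.models)
report = select_top_edges(mean_w, mean_abs_w, atlas, fraction=0.01)
overlap = len({e.edge for e in report.edges} & set(edges))
print(f"top 1% = {report.n_selected} edges; {overlap} of them are planted signal edges")
print(f"long-range (>75 mm): {report.n_long_range}/{report.n_selected}")
print("module pairs of the selected edges:")
summary = module_pair_summary(report, atlas)
for row in summary.sort_values("count", ascending=False).itertuples():
    kind = "within " if row.within_module else "between"
    print(f"  {kind}  {row.module_a:<17} | {row.module_b:<17} : {row.count}")
print("Selected edges concentrating in the modules that carry the planted "
      "signal indicates the weights are interpretable, not noise.")
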