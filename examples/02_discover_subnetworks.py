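"""Full discovery run on a simulated study: score, cross-validate, select.

Simulates a small dual-omics cohort with planted TF-activation signal,
computes interaction scores over the simulated network, picks the shrinkage
by 5-fold cross-validation and prints the selected subnetwork per group.
"""

from netcentroid import SimulationSpec, choose_delta, cross_validate, fit, simulate_dataset
from netcentroid.simulate import prepare_scores

spec = SimulationSpec(n_tf=40, n_targets=150, group_sizes=(15, 15),
                      mean_in_degree=4, mu=1.0, p_as=0.9, seed=8)
ds = simulate_dataset(spec)
bundle, scores = prepare_scores(ds)
print(f"measurable edges: {scores.data.shape[0]}, samples: {scores.data.shape[1]}")

cv = cross_validate(scores, bundle.groups, n_folds=5, seed=8)
delta = choose_delta(cv)
err = cv.table.loc[cv.table["delta"] == delta, "cv_error"].iloc[0]
print(f"chosen delta = {delta:.3f} (of delta_max {cv.model.delta_max:.3f}), "
      f"CV error {err:.3f}")

selection = cv.model.select_subnetwork(delta)
truth = {e.edge_id for e in ds.truth.truth_edges}
for group, df in selection.per_group.items():
    hits = sum(eid in truth for eid in df["edge_id"])
    print(f"group {group}: {len(df)} edges selected, {hits} of them planted signal")
# A low CV error with a small selected edge set means the classifier found a
# sparse subnetwork that separates the groups; the planted-signal overlap
# shows the selection is recovering the simulated biology, not noise.
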