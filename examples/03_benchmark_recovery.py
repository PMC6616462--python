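"""Compare edge-recovery AUC of the network-adjusted classifier against
baselines on simulated data.

Three methods rank the measurable edges of a simulated study by how strongly
they separate the groups: the full network-adjusted statistic, the same
statistic without the neighbourhood adjustment, and a textbook nearest
shrunken centroid on the concatenated node-level matrices.
"""

from netcentroid import SimulationSpec, run_benchmark

spec = SimulationSpec(n_tf=100, n_targets=400, group_sizes=(25, 25),
                      mean_in_degree=5, setting="A", p_as=0.7, seed=4)
result = run_benchmark(spec, n_reps=5)
print(result.summary.to_string(index=False))
# mean_auc is the probability that a randomly chosen planted edge outranks a
# randomly chosen null edge; the network-adjusted method leads because edges
# whose neighbours carry consistent signal are promoted over isolated ones.
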