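"""Fuse three small input clusterings into one consensus partition.

Two clusterings agree perfectly on how to split six samples; a third disagrees
on one sample.  Evidence accumulation turns the agreements into edge weights,
and the threshold sweep picks the partition with the best weighted
modularization quality (wMQ).
"""

from clustfuse import (
    ConsensusParams,
    InputClustering,
    IntegrationScenario,
    build_integration_graph,
    build_support_graph,
    run_consensus,
)

split = {"s1": "L", "s2": "L", "s3": "L", "s4": "R", "s5": "R", "s6": "R"}
dissent = dict(split, s3="R")  # one sample moved

inputs = [
    InputClustering("kmeans.expr", "kmeans", frozenset({"expr"}), dict(split)),
    InputClustering("nmf.expr", "nmf", frozenset({"expr"}), dict(split)),
    InputClustering("kmeans.meth", "kmeans", frozenset({"meth"}), dissent),
]

sg = build_support_graph(inputs)
ig = build_integration_graph(sg, IntegrationScenario.select(inputs))
print(f"integration graph: {len(ig.nodes)} samples, {ig.n_edges} edges, "
      f"max possible supports = {ig.max_supports}")
print(f"supports for the contested pair (s3, s4): {ig.weight('s3', 's4')} "
      "(only the dissenting clustering groups them)")

result = run_consensus(ig, ConsensusParams(), seed=0)
print(f"\nselected: threshold={result.threshold} supports, "
      f"algorithm={result.algorithm}, wMQ={result.wmq:.3f}")
for label, size in sorted(result.cluster_sizes().items()):
    members = sorted(s for s, l in result.assignment.items() if l == label)
    print(f"  consensus cluster {label}: {members}")
# The 2-vote majority wins: s3 stays with s1, s2 despite the dissenting input.
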