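"""Threshold the network, score hubs by maximal clique centrality, and
compute the first-neighbour "alliance" structure of the two pathway seed sets.
"""

import ventnet.hubs as hb
from ventnet import run_pipeline

result = run_pipeline(seed=1)
graph = result.graph
print(f"thresholded graph (TOM > 0.05, iterative degree > 2): "
      f"{graph.graph.number_of_nodes()} nodes, {graph.graph.number_of_edges()} edges")

print("\ntop 5 MCC hubs:")
print(result.hub_table.head(5).to_string(index=False))
print("MCC sums (|C|-1)! over the maximal cliques containing a node, so the "
      "highest scores mark genes embedded in the densest co-expression cores.")

for name, seeds in result.truth.seed_sets.items():
    nbrs = result.neighbor_sets[name]
    true = result.truth.true_neighbors(name)
    tp = len(nbrs & true)
    print(f"\n{name}: {len(seeds)} seed genes -> {len(nbrs)} first neighbours "
          f"(precision {tp / len(nbrs):.2f}, recall {tp / len(true):.2f} vs truth)")

pw = result.alliance.pairwise
print(f"\nshared neighbours between the two pathways: "
      f"{int(pw['shared'].iloc[0])} (Jaccard {pw['jaccard'].iloc[0]:.3f})")
print("A near-empty intersection reproduces the bi-modal organisation: each "
      "metabolic neighbourhood allies with one carbon-fixation pathway.")
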