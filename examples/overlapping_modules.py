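"""Detect overlapping modules on a synthetic connectome with planted truth.

Generates a 120-node correlation matrix in which 30% of nodes belong to two
of four planted modules, runs the full edge-centric pipeline (15% density
threshold -> Tanimoto edge graph -> 20 Louvain instances), and compares the
estimated nodal entropy with the planted dual/single memberships.
"""

import numpy as np

from overlapnet.pipeline import overlapping_modules_pipeline
from overlapnet.synthdata import gen_overlapping_network

corr, truth = gen_overlapping_network(n_nodes=120, n_modules=4, overlap_fraction=0.3, seed=7)
res = overlapping_modules_pipeline(corr, density=0.15, n_instances=20, seed=7)

h = res["node_entropy"]
dual = truth.extra["dual_nodes"]
single = [i for i in range(120) if i not in dual]

print(f"network: {res['network'].n_nodes} nodes, {res['network'].n_edges} edges at 15% density")
print(f"edge graph: {res['edge_graph'].n_edges} edge-vertices, "
      f"{res['edge_graph'].similarity.nnz // 2} similarity links")
print(f"modal module number over 20 instances: {res['modal_n']} (4 node-level blocks planted)")
print(f"mean edge-graph modularity Q: {res['mean_modularity']:.3f}")
print(f"global entropy (mean nodal H): {res['global_entropy']:.3f}")
print(f"mean H, planted dual-membership nodes:   {np.nanmean(h[dual]):.3f}")
print(f"mean H, planted single-membership nodes: {np.nanmean(h[single]):.3f}")
print("-> dual-membership nodes spread their edges over more modules, so their")
print("   normalized entropy is higher; H=0 means all edges in one module.")
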