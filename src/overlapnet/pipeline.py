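"""End-to-end convenience wrapper: correlation matrix -> overlap summary."""

from __future__ import annotations

from .netio import CorrelationMatrix, threshold_by_density
from .edgegraph import build_edge_graph
from .modules import run_instances, consensus_partition
from .overlap import summarize_instances, entropy_map, node_distribution


def overlapping_modules_pipeline(corr: CorrelationMatrix, density: float = 0.15,
                                 n_instances: int = 100, seed: int = 0,
                                 consensus: bool = False, resolution: float = 1.0) -> dict:
    """Run threshold -> edge graph -> Louvain ensemble -> nodal overlap.

    Returns a dict with the thresholded network, edge graph, ensemble (and
    optionally the consensus partition), the per-node mean entropy map,
    modal module number and mean modularity.  With ``consensus=True`` the
    entropy map and node profiles come from the consensus partition instead
    of the instance average, as used for group-level topography.
    """
    net = threshold_by_density(corr, density)
    eg = build_edge_graph(net)
    ens = run_instances(eg, n_instances=n_instances, base_seed=seed)
    out = {
        "network": net,
        "edge_graph": eg,
        "ensemble": ens,
        **summarize_instances(ens, net),
    }
    if consensus:
        part = consensus_partition(eg, n_instances=n_instances, base_seed=seed,
                                   resolution=resolution)
        out["consensus"] = part
        out["consensus_entropy"] = entropy_map(part, net)
        out["consensus_profiles"] = node_distribution(part, net)
    return out
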