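"""Node-level overlap quantities derived from an edge partition.

A node inherits partial membership in every module its incident edges were
assigned to.  With p_ik the proportion of node i's edges in module k, the
extent of overlap is the Shannon entropy of that distribution normalized by
log2 of the node's involved-module count:

    H_i = -sum_k p_ik log2 p_ik / log2 n_i

so H_i = 0 when all edges sit in one module and H_i = 1 when they are
spread uniformly.  A node with edges in >= 2 modules is an *overlapping*
region.  Nodes left edgeless by thresholding carry a missing flag and are
excluded from all means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .modules import EdgePartition, InstanceEnsemble
from .netio import Parcellation, WeightedNetwork, SYSTEMS

__all__ = [
    "NodeOverlapProfile",
    "ModuleMap",
    "node_distribution",
    "nodal_entropy",
    "involved_number",
    "entropy_map",
    "summarize_instances",
    "module_maps",
    "match_modules",
    "system_composition",
    "system_entropy",
    "write_entropy_map",
    "write_module_maps",
]


@dataclass
class NodeOverlapProfile:
    node: int
    proportions: dict[int, float]  # module id -> p_ik
    entropy: float
    n_involved: int
    missing: bool = False


@dataclass
class ModuleMap:
    """Per-node proportion of edges assigned to one module; NaN = missing node."""

    module: int
    values: np.ndarray


def nodal_entropy(proportions: dict[int, float] | np.ndarray) -> float:
    """Normalized entropy of a module-affiliation distribution, in [0, 1].

    Uses the convention 0*log 0 = 0; a single involved module gives 0.
    """
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict) else proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    p = p[p > 0]
    n = p.size
    if n <= 1:
        return 0.0
    h = -float(np.sum(p * np.log2(p)))
    return h / math.log2(n)


def involved_number(proportions: dict[int, float] | np.ndarray) -> int:
    """Count of modules with nonzero edge share; >= 2 marks an overlapping node."""
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict) else proportions, dtype=float)
    return int(np.count_nonzero(p > 0))


def node_distribution(p: EdgePartition, net: WeightedNetwork) -> list[NodeOverlapProfile]:
    """Per-node module-affiliation proportions, entropy and involvement count."""
    edges = net.edge_list()
    if p.labels.shape[0] != len(edges):
        raise ValueError("partition and network disagree on the edge count")
    per_node: list[dict[int, int]] = [dict() for _ in range(net.n_nodes)]
    for e_idx, (i, j) in enumerate(edges):
        mod = int(p.labels[e_idx])
        for node in (i, j):
            per_node[node][mod] = per_node[node].get(mod, 0) + 1
    out: list[NodeOverlapProfile] = []
    for node, counts in enumerate(per_node):
        if not counts:
            out.append(NodeOverlapProfile(node=node, proportions={}, entropy=float("nan"),
                                          n_involved=0, missing=True))
            continue
        k_i = sum(counts.values())
        props = {mod: c / k_i for mod, c in sorted(counts.items())}
        out.append(NodeOverlapProfile(node=node, proportions=props,
                                      entropy=nodal_entropy(props),
                                      n_involved=involved_number(props)))
    return out


def entropy_map(p: EdgePartition, net: WeightedNetwork) -> np.ndarray:
    """Per-node normalized entropy vector; NaN for edgeless nodes."""
    return np.array([prof.entropy for prof in node_distribution(p, net)])


def summarize_instances(ens: InstanceEnsemble, net: WeightedNetwork) -> dict:
    """Ensemble averages: per-node mean entropy, global entropy, mean Q.

    Entropy is normalized per instance before averaging; the global value is
    the mean of the averaged map over non-missing nodes.
    """
    maps = np.vstack([entropy_map(p, net) for p in ens.partitions])
    mean_map = maps.mean(axis=0)  # NaN propagates for missing nodes
    valid = ~np.isnan(mean_map)
    return {
        "node_entropy": mean_map,
        "global_entropy": float(mean_map[valid].mean()) if valid.any() else float("nan"),
        "mean_modularity": ens.mean_modularity,
        "modal_n": ens.modal_n,
    }


def module_maps(p: EdgePartition, net: WeightedNetwork) -> list[ModuleMap]:
    """One spatial map per module: map k at node i is p_ik (NaN if edgeless)."""
    profiles = node_distribution(p, net)
    mods = sorted({int(m) for m in np.unique(p.labels)})
    maps = []
    for mod in mods:
        vals = np.full(net.n_nodes, np.nan)
        for prof in profiles:
            if not prof.missing:
                vals[prof.node] = prof.proportions.get(mod, 0.0)
        maps.append(ModuleMap(module=mod, values=vals))
    return maps


def write_entropy_map(profiles: list[NodeOverlapProfile], path) -> None:
    """Entropy map TSV: node_id, entropy, n_involved, missing."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("node_id\tentropy\tn_involved\tmissing\n")
        for p in profiles:
            h = "" if p.missing else f"{p.entropy:.10g}"
            fh.write(f"{p.node}\t{h}\t{p.n_involved}\t{int(p.missing)}\n")


def write_module_maps(maps: list[ModuleMap], path) -> None:
    """Module maps as a wide TSV: one node row, one column per module."""
    import pandas as pd

    df = pd.DataFrame({f"module_{m.module}": m.values for m in maps})
    df.insert(0, "node_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def match_modules(maps_a: list[ModuleMap], maps_b: list[ModuleMap]) -> list[dict]:
    """Match each reference map in ``maps_a`` to its most similar map in ``maps_b``.

    Similarity is the Pearson correlation across nodes.  Matches may be
    many-to-one.  A constant reference map yields a missing match.
    """
    out = []
    for ma in maps_a:
        rs = np.array([_pearson(ma.values, mb.values) for mb in maps_b])
        if np.all(np.isnan(rs)):
            out.append({"module_a": ma.module, "module_b": None, "r": float("nan")})
            continue
        best = int(np.nanargmax(rs))
        out.append({"module_a": ma.module, "module_b": maps_b[best].module, "r": float(rs[best])})
    return out


def system_composition(map_: ModuleMap, parc: Parcellation, membership_threshold: float = 0.0) -> dict[str, float]:
    """Percentage of a module's member nodes falling in each functional system.

    A node is a member when its edge share in the module exceeds the
    threshold (default: any edge).  Percentages sum to 100.
    """
    if len(parc.systems) != map_.values.shape[0]:
        raise ValueError("parcellation does not cover the map's nodes")
    members = [i for i, v in enumerate(map_.values) if not np.isnan(v) and v > membership_threshold]
    if not members:
        return {s: float("nan") for s in SYSTEMS}
    counts = {s: 0 for s in SYSTEMS}
    for i in members:
        counts[parc.system_of(i)] += 1
    return {s: 100.0 * c / len(members) for s, c in counts.items()}


def system_entropy(entropy_values: np.ndarray, parc: Parcellation) -> dict[str, float]:
    """Mean entropy per functional system plus the global mean ('GLOBAL')."""
    vals = np.asarray(entropy_values, dtype=float)
    if len(parc.systems) != vals.shape[0]:
        raise ValueError("parcellation does not cover the entropy map")
    out: dict[str, float] = {}
    for s in SYSTEMS:
        idx = [i for i, lab in enumerate(parc.systems) if lab == s]
        sub = vals[idx]
        sub = sub[~np.isnan(sub)]
        out[s] = float(sub.mean()) if sub.size else float("nan")
    valid = vals[~np.isnan(vals)]
    out["GLOBAL"] = float(valid.mean()) if valid.size else float("nan")
    return out
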