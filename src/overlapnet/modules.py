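"""Module detection on the edge graph.

Louvain is a greedy heuristic, so repeated runs with different seeds give
slightly different partitions.  The module number of a network is defined as
the modal module count over an ensemble of runs (100 by default), and other
quantities are averaged across the ensemble.  For group-level analyses a
consensus procedure is used: the ensemble's module co-occurrence matrix (the
fraction of runs assigning each edge pair to the same module) is itself
re-clustered, iterating until every run of an iteration returns the same
partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .edgegraph import EdgeGraph, edge_graph_from_similarity

__all__ = [
    "EdgePartition",
    "InstanceEnsemble",
    "CooccurrenceMatrix",
    "louvain_partition",
    "modularity",
    "run_instances",
    "cooccurrence",
    "consensus_partition",
    "canonical_labels",
    "write_partition",
    "ensemble_summary",
]

DEFAULT_N_INSTANCES = 100


@dataclass
class EdgePartition:
    """Assignment of every edge-graph vertex (i.e., network edge) to a module."""

    labels: np.ndarray  # edge index -> module id, 1..n_modules
    n_modules: int
    modularity: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.min() < 1:
            raise ValueError("module ids must start at 1")

    def module_of(self, edge_index: int) -> int:
        return int(self.labels[edge_index])


@dataclass
class InstanceEnsemble:
    partitions: list[EdgePartition]
    modal_n: int = field(init=False)
    mean_modularity: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("ensemble needs at least one partition")
        counts = Counter(p.n_modules for p in self.partitions)
        top = max(counts.values())
        # tie on frequency -> smaller module number (parsimony)
        self.modal_n = min(n for n, c in counts.items() if c == top)
        self.mean_modularity = float(np.mean([p.modularity for p in self.partitions]))


@dataclass
class CooccurrenceMatrix:
    values: np.ndarray  # edge x edge, fraction of instances co-assigned

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValueError("co-occurrence matrix must be symmetric")
        self.values = v


def write_partition(p: EdgePartition, path) -> None:
    """Partition TSV: one (edge_id, module) row per edge."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("edge_id\tmodule\n")
        for idx, lab in enumerate(p.labels):
            fh.write(f"{idx}\t{lab}\n")


def ensemble_summary(ens: InstanceEnsemble) -> dict:
    """JSON-ready ensemble summary: modal n, mean Q, per-instance n/Q/seed."""
    return {
        "modal_n": ens.modal_n,
        "mean_modularity": ens.mean_modularity,
        "instances": [
            {"seed": p.seed, "n_modules": p.n_modules, "modularity": p.modularity}
            for p in ens.partitions
        ],
    }


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules by first occurrence, making label permutations comparable."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for idx, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[idx] = mapping[lab]
    return out


def _to_nx(eg: EdgeGraph) -> nx.Graph:
    g = nx.from_scipy_sparse_array(eg.similarity)
    return g


def modularity(eg: EdgeGraph, p: EdgePartition) -> float:
    """Weighted Newman-Girvan modularity of a partition on the edge graph.

    Q = (1/2m) sum_ij [w_ij - s_i s_j / (2m)] delta(c_i, c_j), with s the
    vertex strengths and m the total weight.
    """
    w = eg.similarity
    if p.labels.shape[0] != eg.n_edges:
        raise ValueError("partition does not cover the edge graph")
    two_m = float(w.sum())
    if two_m == 0:
        raise ValueError("modularity undefined for a zero-weight graph")
    strengths = np.asarray(w.sum(axis=1)).ravel()
    q = 0.0
    labels = p.labels
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        w_in = float(w[np.ix_(idx, idx)].sum())  # counts both (i,j) and (j,i)
        s_tot = float(strengths[idx].sum())
        q += w_in / two_m - (s_tot / two_m) ** 2
    return q


def louvain_partition(eg: EdgeGraph, seed: int, resolution: float = 1.0) -> EdgePartition:
    """One seeded Louvain run on the edge graph; deterministic per seed."""
    if eg.n_edges == 0:
        raise ValueError("cannot partition an empty edge graph")
    g = _to_nx(eg)
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=int(seed))
    labels = np.zeros(eg.n_edges, dtype=int)
    for mod_id, members in enumerate(comms, start=1):
        for v in members:
            labels[v] = mod_id
    labels = canonical_labels(labels)
    part = EdgePartition(labels=labels, n_modules=int(labels.max()), modularity=0.0, seed=int(seed))
    part.modularity = modularity(eg, part)
    return part


def run_instances(eg: EdgeGraph, n_instances: int = DEFAULT_N_INSTANCES, base_seed: int = 0,
                  resolution: float = 1.0) -> InstanceEnsemble:
    """Louvain ensemble with seeds base_seed .. base_seed + n_instances - 1."""
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    parts = [louvain_partition(eg, seed=base_seed + k, resolution=resolution) for k in range(n_instances)]
    return InstanceEnsemble(partitions=parts)


def cooccurrence(ens: InstanceEnsemble) -> CooccurrenceMatrix:
    """Fraction of ensemble runs co-assigning each pair of edges; diagonal 1."""
    m = ens.partitions[0].labels.shape[0]
    acc = np.zeros((m, m), dtype=float)
    for p in ens.partitions:
        acc += p.labels[:, None] == p.labels[None, :]
    acc /= len(ens.partitions)
    np.fill_diagonal(acc, 1.0)
    return CooccurrenceMatrix(values=acc)


def _all_identical(ens: InstanceEnsemble) -> bool:
    ref = canonical_labels(ens.partitions[0].labels)
    return all(np.array_equal(ref, canonical_labels(p.labels)) for p in ens.partitions[1:])


def consensus_partition(eg: EdgeGraph, n_instances: int = DEFAULT_N_INSTANCES, max_iter: int = 20,
                        base_seed: int = 0, resolution: float = 1.0) -> EdgePartition:
    """Iterated co-occurrence consensus clustering of the edge graph.

    Runs a Louvain ensemble, re-clusters the resulting co-occurrence matrix
    (taken directly as a dense weighted graph, no thresholding), and repeats
    until every run of an iteration agrees up to a label permutation.  The
    returned partition carries its modularity on the *original* edge graph
    and provenance in ``consensus_iterations`` / ``converged`` attributes.
    If ``max_iter`` is exhausted the most frequent partition of the last
    iteration is returned with ``converged = False``.
    """
    current = eg
    ens: InstanceEnsemble | None = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        ens = run_instances(current, n_instances=n_instances,
                            base_seed=base_seed + (iterations - 1) * n_instances,
                            resolution=resolution)
        if _all_identical(ens):
            converged = True
            break
        co = cooccurrence(ens)
        current = edge_graph_from_similarity(co.values, edges=eg.edges, n_nodes=eg.n_nodes)
    assert ens is not None
    if converged:
        chosen = ens.partitions[0]
    else:
        keys = [tuple(canonical_labels(p.labels)) for p in ens.partitions]
        modal_key = Counter(keys).most_common(1)[0][0]
        chosen = ens.partitions[keys.index(modal_key)]
    labels = canonical_labels(chosen.labels)
    result = EdgePartition(labels=labels, n_modules=int(labels.max()), modularity=0.0, seed=base_seed)
    result.modularity = modularity(eg, result)
    result.converged = converged
    result.consensus_iterations = iterations
    return result
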