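"""Weighted edge (line) graph construction with Tanimoto interedge similarity.

Vertices of the edge graph are the retained edges of a weighted network.
Two edges e_ik and e_jk that share a node k are linked with weight equal to
the Tanimoto similarity of the *modified connectivity profiles* of the two
non-shared endpoints i and j:

    S(e_ik, e_jk) = a_i . a_j / (|a_i|^2 + |a_j|^2 - a_i . a_j)

where a_i is node i's connection-weight vector whose own diagonal entry is
set to its mean retained-edge weight.  That nonzero diagonal makes the
similarity well defined when i and j are themselves directly connected.
Edge pairs with no shared node are given similarity zero and are not stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .netio import WeightedNetwork

__all__ = ["ConnectivityProfile", "EdgeGraph", "modified_profile", "tanimoto", "build_edge_graph"]


@dataclass
class ConnectivityProfile:
    """Modified connectivity profile a_i of one node."""

    owner: int
    values: np.ndarray
    disconnected: bool = False


@dataclass
class EdgeGraph:
    """Edges-as-vertices graph with sparse symmetric Tanimoto similarity.

    ``edges`` lists the underlying network's edges as (i, j), i < j, sorted
    lexicographically; row/column e of ``similarity`` corresponds to
    ``edges[e]``.  Only pairs sharing exactly one node carry a stored entry;
    the diagonal is zero.
    """

    edges: list[tuple[int, int]]
    similarity: sp.csr_matrix
    n_nodes: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        """Sum of similarity over unordered vertex pairs (m in modularity)."""
        return float(self.similarity.sum()) / 2.0

    def to_dense(self) -> np.ndarray:
        return self.similarity.toarray()


def modified_profile(net: WeightedNetwork, i: int) -> ConnectivityProfile:
    """Connection-weight vector of node i with diagonal = mean edge weight."""
    n = net.n_nodes
    if not (0 <= i < n):
        raise IndexError(f"node index {i} out of range for {n} nodes")
    row = net.adjacency[i].astype(float).copy()
    k = int(np.count_nonzero(row))
    if k == 0:
        return ConnectivityProfile(owner=i, values=np.zeros(n), disconnected=True)
    row[i] = row.sum() / k
    return ConnectivityProfile(owner=i, values=row)


def tanimoto(a: ConnectivityProfile | np.ndarray, b: ConnectivityProfile | np.ndarray) -> float:
    """Tanimoto coefficient a.b / (|a|^2 + |b|^2 - a.b), in [0, 1]."""
    va = a.values if isinstance(a, ConnectivityProfile) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, ConnectivityProfile) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("profiles must have equal length")
    dot = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto similarity undefined for two zero profiles")
    return dot / denom


def build_edge_graph(net: WeightedNetwork) -> EdgeGraph:
    """Build the Tanimoto-weighted edge graph of a thresholded network.

    Iterates over nodes and enumerates pairs of incident edges, so the cost
    is O(sum_k k_deg^2) rather than O(E^2).  Profiles are computed once per
    node.  In a simple graph two distinct edges share at most one node, so
    each linked pair is visited exactly once (at its shared node).
    """
    edges = net.edge_list()
    if len(edges) < 2:
        raise ValueError("edge graph needs a network with at least 2 edges")
    edge_index = {e: idx for idx, e in enumerate(edges)}
    n = net.n_nodes
    profiles = [modified_profile(net, i).values for i in range(n)]

    incident: list[list[int]] = [[] for _ in range(n)]
    for idx, (i, j) in enumerate(edges):
        incident[i].append(idx)
        incident[j].append(idx)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for k in range(n):
        inc = incident[k]
        for a_pos in range(len(inc)):
            ea = inc[a_pos]
            ia, ja = edges[ea]
            u = ja if ia == k else ia  # non-shared endpoint of ea
            for b_pos in range(a_pos + 1, len(inc)):
                eb = inc[b_pos]
                ib, jb = edges[eb]
                v = jb if ib == k else ib
                s = tanimoto(profiles[u], profiles[v])
                rows.append(ea)
                cols.append(eb)
                vals.append(s)
    m = len(edges)
    sim = sp.coo_matrix((vals, (rows, cols)), shape=(m, m))
    sim = (sim + sim.T).tocsr()
    return EdgeGraph(edges=edges, similarity=sim, n_nodes=n)


def write_edge_graph(eg: EdgeGraph, path) -> None:
    """Serialize as a similarity TSV (edge_a, edge_b, similarity) plus an
    edge-index table <path>.edges.tsv (edge_id, i, j)."""
    from pathlib import Path

    path = Path(path)
    coo = sp.triu(eg.similarity, k=1).tocoo()
    with path.open("w") as fh:
        fh.write("edge_a\tedge_b\tsimilarity\n")
        for a, b, s in zip(coo.row, coo.col, coo.data):
            fh.write(f"{a}\t{b}\t{s:.10g}\n")
    with path.with_suffix(path.suffix + ".edges.tsv").open("w") as fh:
        fh.write("edge_id\ti\tj\n")
        for idx, (i, j) in enumerate(eg.edges):
            fh.write(f"{idx}\t{i}\t{j}\n")


def read_edge_graph(path) -> EdgeGraph:
    """Read an edge graph written by :func:`write_edge_graph`."""
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    sim_df = pd.read_csv(path, sep="\t")
    edge_df = pd.read_csv(path.with_suffix(path.suffix + ".edges.tsv"), sep="\t")
    edges = list(zip(edge_df["i"].astype(int), edge_df["j"].astype(int)))
    m = len(edges)
    sim = sp.coo_matrix((sim_df["similarity"], (sim_df["edge_a"], sim_df["edge_b"])), shape=(m, m))
    sim = (sim + sim.T).tocsr()
    n_nodes = 1 + max(max(e) for e in edges)
    return EdgeGraph(edges=edges, similarity=sim, n_nodes=n_nodes)


def edge_graph_from_similarity(similarity: np.ndarray | sp.spmatrix, edges: list[tuple[int, int]] | None = None,
                               n_nodes: int | None = None) -> EdgeGraph:
    """Wrap a precomputed edge-by-edge similarity matrix as an :class:`EdgeGraph`.

    Used for planted-block benchmarks and for consensus iterations, where the
    similarity matrix is a co-occurrence matrix rather than Tanimoto values.
    If ``edges`` is omitted, synthetic placeholder edges (0, e+1) are used.
    """
    sim = sp.csr_matrix(similarity)
    m = sim.shape[0]
    sim = sim.tolil()
    sim.setdiag(0)
    sim = sim.tocsr()
    sim.eliminate_zeros()
    if edges is None:
        edges = [(0, e + 1) for e in range(m)]
        n_nodes = m + 1
    if n_nodes is None:
        n_nodes = 1 + max(max(e) for e in edges)
    return EdgeGraph(edges=list(edges), similarity=sim, n_nodes=n_nodes)
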