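"""Reading correlation matrices and building thresholded weighted networks.

A functional connectome arrives as a dense node x node Pearson correlation
matrix.  Analysis operates on a sparse nonnegative *weighted network* obtained
by keeping only the strongest positive correlations up to a target connection
density (the fraction of all N(N-1)/2 possible undirected edges that are
retained).  Negative correlations are discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "WeightedNetwork",
    "Parcellation",
    "load_correlation_matrix",
    "load_parcellation",
    "threshold_by_density",
    "build_group_network",
    "write_network",
    "read_network",
]

SYSTEMS = ("VIS", "SM", "DA", "VA", "LIM", "FP", "DM", "SUB")

_SYM_TOL = 1e-10


@dataclass
class CorrelationMatrix:
    """Square symmetric correlation matrix with unit diagonal."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if v.shape[0] < 3:
            raise ValueError("correlation matrix must have dimension >= 3")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("correlation matrix must be symmetric within 1e-10")
        self.values = v
        if len(self.node_ids) != v.shape[0]:
            raise ValueError("node_ids length must match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightedNetwork:
    """Thresholded nonnegative symmetric connectivity, zero diagonal.

    ``adjacency`` stores the retained correlation weights A_ij; a node's
    degree k_i is its number of retained edges.  ``density`` is the achieved
    edge fraction; ``shortfall`` is set when fewer positive correlations
    existed than the target density demanded.
    """

    adjacency: np.ndarray
    density: float
    node_ids: list[str]
    shortfall: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(a, a.T, atol=_SYM_TOL):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if np.any(a < 0):
            raise ValueError("adjacency weights must be nonnegative")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def degrees(self) -> np.ndarray:
        """Number of retained edges per node (k_i)."""
        return (self.adjacency > 0).sum(axis=1)

    def edge_list(self) -> list[tuple[int, int]]:
        """Retained edges as (i, j), i < j, in lexicographic order."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def disconnected_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.degrees() == 0)


@dataclass
class Parcellation:
    """Node -> functional-system lookup with optional 3-D coordinates (mm)."""

    node_ids: list[str]
    systems: list[str]
    coordinates: np.ndarray | None = None
    names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.systems) != len(self.node_ids):
            raise ValueError("one system label per node required")
        bad = sorted(set(self.systems) - set(SYSTEMS))
        if bad:
            raise ValueError(f"unknown system labels: {bad}")
        if self.coordinates is not None:
            c = np.asarray(self.coordinates, dtype=float)
            if c.shape != (len(self.node_ids), 3):
                raise ValueError("coordinates must be (n_nodes, 3)")
            if not np.all(np.isfinite(c)):
                raise ValueError("coordinates must be finite")
            self.coordinates = c

    def system_of(self, index: int) -> str:
        return self.systems[index]

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between node coordinates."""
        if self.coordinates is None:
            raise ValueError("parcellation has no coordinates")
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.coordinates))


def _looks_like_header(first_row: list[str]) -> bool:
    for cell in first_row:
        try:
            float(cell)
        except ValueError:
            return True
    return False


def load_correlation_matrix(path: str | Path, delimiter: str | None = None) -> CorrelationMatrix:
    """Load a dense correlation matrix from delimited text.

    Accepts comma- or whitespace-delimited values with an optional single
    header row of node labels.  The matrix is symmetrized as (M + M')/2 and
    the diagonal forced to 1.  Node ids default to 0-based ordinals.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = delimiter
    if sep is None:
        sep = "," if "," in lines[0] else None  # None -> whitespace split
    rows = [ln.split(sep) if sep else ln.split() for ln in lines]
    node_ids: list[str] | None = None
    if _looks_like_header(rows[0]):
        node_ids = [c.strip() for c in rows[0]]
        rows = rows[1:]
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise ValueError(f"{path}: not a square matrix ({n} rows)")
    values = np.empty((n, n), dtype=float)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r):
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell at row {i}, col {j}: {cell!r}") from exc
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    return CorrelationMatrix(values=values, node_ids=node_ids)


def load_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation TSV with columns node_id, name, system[, x, y, z]."""
    df = pd.read_csv(path, sep="\t")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return Parcellation(
        node_ids=[str(v) for v in df["node_id"]],
        systems=[str(v) for v in df["system"]],
        coordinates=coords,
        names=[str(v) for v in df["name"]] if "name" in df.columns else None,
    )


def target_edge_count(n_nodes: int, density: float) -> int:
    """Edges to retain at a density: ceil(density * N(N-1)/2)."""
    return math.ceil(density * n_nodes * (n_nodes - 1) / 2)


def threshold_by_density(corr: CorrelationMatrix, density: float) -> WeightedNetwork:
    """Keep the strongest positive correlations up to the target density.

    Retains the E = ceil(density * N(N-1)/2) largest positive off-diagonal
    correlations as edge weights; everything else becomes zero.  Ties at the
    cut are broken by lexicographic (i, j) order.  If fewer than E positive
    correlations exist, all positives are kept and ``shortfall`` is set.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = corr.n_nodes
    target = target_edge_count(n, density)
    iu, ju = np.triu_indices(n, k=1)
    w = corr.values[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    # stable sort by descending weight then (i, j)
    order = np.lexsort((ju, iu, -w))
    keep = order[:target]
    shortfall = keep.size < target
    adj = np.zeros((n, n), dtype=float)
    adj[iu[keep], ju[keep]] = w[keep]
    adj += adj.T
    achieved = keep.size / (n * (n - 1) / 2)
    return WeightedNetwork(adjacency=adj, density=achieved, node_ids=list(corr.node_ids), shortfall=shortfall)


def build_group_network(matrices: list[CorrelationMatrix], density: float) -> WeightedNetwork:
    """Average raw correlation matrices elementwise, then threshold.

    All matrices must share the same node ids in the same order.  Averaging
    is done on the raw correlations (no Fisher-z transform).
    """
    if not matrices:
        raise ValueError("need at least one correlation matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.node_ids != ref.node_ids:
            raise ValueError("correlation matrices have mismatched node ids")
    mean = np.mean([m.values for m in matrices], axis=0)
    return threshold_by_density(CorrelationMatrix(values=mean, node_ids=list(ref.node_ids)), density)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write an edge-list TSV (i, j, weight) plus a JSON sidecar."""
    path = Path(path)
    edges = net.edge_list()
    with path.open("w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in edges:
            fh.write(f"{i}\t{j}\t{net.adjacency[i, j]:.10g}\n")
    sidecar = {"density": net.density, "n_nodes": net.n_nodes, "n_edges": len(edges), "shortfall": net.shortfall}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_network(path: str | Path) -> WeightedNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n = int(meta["n_nodes"])
    adj = np.zeros((n, n), dtype=float)
    adj[df["i"], df["j"]] = df["weight"]
    adj += adj.T
    return WeightedNetwork(
        adjacency=adj,
        density=float(meta["density"]),
        node_ids=[str(i) for i in range(n)],
        shortfall=bool(meta.get("shortfall", False)),
    )
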