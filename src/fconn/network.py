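"""Connectivity-matrix construction and proportional thresholding.

Subject networks are built as Pearson correlations between ROI time
series (valid frames only), Fisher z-transformed, then binarized by
proportional thresholding: at sparsity ``s`` the ``round(s * N(N-1)/2)``
strongest (signed) z values become edges. Group-level networks are
occurrence graphs: an edge enters the group graph when it is present in
at least a fraction tau of the subjects' binarized networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import RoiTimeSeriesSet


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("z must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("z must be symmetric")
        off = self.z[~np.eye(self.z.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal z values must be finite")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryGraph:
    """Undirected simple graph as a dense 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.diag(a).any():
            raise ValueError("self-loops are not allowed")
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.stack([i, j], axis=1)


@dataclass
class SparsityGrid:
    """Ordered sparsity fractions, default 10%..30% in 1% steps."""

    values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.10, 0.301, 0.01), 2)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if not np.all(np.diff(self.values) > 0):
            raise ValueError("grid values must be strictly increasing")
        if self.values[0] <= 0 or self.values[-1] >= 1:
            raise ValueError("grid values must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def correlation_matrix(ts: RoiTimeSeriesSet) -> ConnectivityMatrix:
    """Pearson correlation over valid frames, Fisher z-transformed.

    |r| values of 1 (numerically degenerate node pairs) are clipped to
    1 - 1e-7 before atanh so z stays finite; the diagonal is set to 0.
    """
    data = ts.data[ts.valid_mask]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 valid frames")
    sd = data.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance node(s): {dead.tolist()}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2
    return ConnectivityMatrix(z=z)


def edge_count_for_sparsity(n_nodes: int, sparsity: float) -> int:
    """round-half-away-from-zero of sparsity * N(N-1)/2."""
    e_max = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * e_max + 0.5))


def binarize(cm: ConnectivityMatrix, sparsity: float) -> BinaryGraph:
    """Keep the E strongest off-diagonal z values as edges.

    Ties at the cut are broken by ascending (i, j) lexicographic node
    order, which makes the edge sets across sparsities nested.
    """
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must be in (0, 1)")
    n = cm.n_nodes
    e = edge_count_for_sparsity(n, sparsity)
    if e == 0:
        raise ValueError(f"sparsity {sparsity} yields zero edges for {n} nodes")
    iu = np.triu_indices(n, 1)
    zvals = cm.z[iu]
    order = np.lexsort((iu[1], iu[0], -zvals))  # z desc, then (i, j) asc
    keep = order[:e]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=sparsity)


def group_occurrence_graph(graphs: list[BinaryGraph], tau: float) -> BinaryGraph:
    """Group-averaged network by edge occurrence.

    An edge is kept when it appears in at least ceil(tau * n_subjects)
    individual binarized networks.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    if not (0 < tau <= 1):
        raise ValueError("tau must be in (0, 1]")
    n = graphs[0].n_nodes
    if any(g.n_nodes != n for g in graphs):
        raise ValueError("all graphs must share the same node set")
    counts = np.zeros((n, n), dtype=np.int64)
    for g in graphs:
        counts += g.adjacency
    thr = int(np.ceil(tau * len(graphs) - 1e-12))
    adj = (counts >= thr).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    e_max = n * (n - 1) / 2
    achieved = float(adj.sum() / 2 / e_max)
    return BinaryGraph(adjacency=adj, sparsity=achieved)


def fisher_z_stack(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Stack subject z matrices into a subjects x nodes x nodes array."""
    return np.stack([m.z for m in matrices])
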