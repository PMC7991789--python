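"""Global and nodal topology of binary graphs.

Implements the standard small-world battery on undirected binary
graphs: clustering coefficient Cp, characteristic path length Lp
(largest connected component), global efficiency, local efficiency,
nodal degree and nodal efficiency, plus normalization against
degree-preserving rewired null networks (gamma = Cp/Cp_rand,
lambda = Lp/Lp_rand, sigma = gamma/lambda) and trapezoidal AUC
integration of metric curves over a threshold grid.

Distances are computed by level-synchronous BFS expressed as dense
boolean matrix products, which is fast at connectome scale (a few
hundred nodes); the double-edge-swap null kernel is numba-compiled
because normalization requires thousands of rewired replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import BinaryGraph, SparsityGrid


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    gamma: float
    lam: float
    sigma: float
    e_glob: float
    e_loc: float
    cp_rand: float
    lp_rand: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp,
            "lp": self.lp,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "e_glob": self.e_glob,
            "e_loc": self.e_loc,
        }


#: Metric names in reporting order (the seven global measures).
GLOBAL_METRIC_NAMES = ("cp", "lp", "gamma", "lambda", "sigma", "e_glob", "e_loc")


@dataclass
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray


@dataclass
class MetricCurve:
    """Metric values over a threshold grid plus the trapezoidal AUC."""

    grid: np.ndarray
    values: np.ndarray
    auc: float


def distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of a binary graph (np.inf where
    disconnected, 0 on the diagonal), via repeated boolean products."""
    n = adj.shape[0]
    a = adj.astype(bool)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    reach = a | np.eye(n, dtype=bool)
    frontier = reach
    d = 1
    af = a.astype(np.float32)
    while True:
        d += 1
        nxt = (frontier.astype(np.float32) @ af) > 0
        new = nxt & ~reach
        if not new.any():
            break
        dist[new] = d
        reach |= new
        frontier = reach
        if d > n:
            break
    return dist


def clustering_coefficient(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering: 2*triangles_i / (k_i (k_i - 1)), 0 for k<2."""
    a = adj.astype(np.float32)
    # triangle counts are small integers, exact in float32; divide in float64
    deg = a.sum(axis=1).astype(np.float64)
    tri = ((a @ a) * a).sum(axis=1).astype(np.float64) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.maximum(denom, 1.0), 0.0)
    return c


def _lp_largest_component(dist: np.ndarray) -> float:
    """Mean shortest path over connected pairs of the largest component."""
    finite = np.isfinite(dist)
    comp_size = finite.sum(axis=1)  # includes the node itself
    members = finite[int(np.argmax(comp_size))]
    sub = dist[np.ix_(members, members)]
    m = members.sum()
    if m < 2:
        return 0.0
    off = ~np.eye(int(m), dtype=bool)
    return float(sub[off].mean())


def global_efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbor-induced subgraph (0 for nodes with fewer than 2 neighbors)."""
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[i] = global_efficiency_from_dist(distance_matrix(sub))
    return float(vals.mean())


def nodal_metrics(g: BinaryGraph) -> NodalMetrics:
    """Nodal degree and nodal efficiency (mean inverse distance to all
    other nodes; disconnected pairs contribute 0)."""
    adj = np.asarray(g.adjacency)
    degree = adj.sum(axis=1).astype(int)
    dist = distance_matrix(adj)
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(degree=degree, efficiency=eff)


# ---------------------------------------------------------------------------
# degree-preserving rewiring null model


@njit(cache=True)
def _swap_kernel(edges, n_nodes, n_swaps, max_tries, seed):  # pragma: no cover
    n_edges = edges.shape[0]
    present = np.zeros(n_nodes * n_nodes, dtype=np.uint8)
    for k in range(n_edges):
        present[edges[k, 0] * n_nodes + edges[k, 1]] = 1
    # inline xorshift64 PRNG: the kernel runs tens of thousands of times
    # per analysis, so per-draw overhead matters
    state = np.uint64(seed) * np.uint64(2685821657736338717) + np.uint64(
        1442695040888963407
    )
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)
    done = 0
    tries = 0
    ne = np.uint64(n_edges)
    while done < n_swaps and tries < max_tries:
        tries += 1
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        r1 = state
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        r2 = state
        e1 = np.int64(r1 % ne)
        e2 = np.int64(r2 % ne)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if (r1 >> np.uint64(63)) & np.uint64(1):
            c, d = d, c
        if a == c or b == d:
            continue
        i1, j1 = (a, c) if a < c else (c, a)
        i2, j2 = (b, d) if b < d else (d, b)
        k1 = i1 * n_nodes + j1
        k2 = i2 * n_nodes + j2
        if k1 == k2 or present[k1] == 1 or present[k2] == 1:
            continue
        present[edges[e1, 0] * n_nodes + edges[e1, 1]] = 0
        present[edges[e2, 0] * n_nodes + edges[e2, 1]] = 0
        present[k1] = 1
        present[k2] = 1
        edges[e1, 0], edges[e1, 1] = i1, j1
        edges[e2, 0], edges[e2, 1] = i2, j2
        done += 1
    return done


def rewire_null(
    g: BinaryGraph, n_swaps_per_edge: int = 10, seed: int | None = None
) -> BinaryGraph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Swaps that would create self-loops or multi-edges are rejected, so
    the degree sequence is preserved exactly. Graphs admitting no valid
    swap (e.g. a triangle) are returned unchanged once the try budget is
    exhausted.
    """
    edges = g.edge_list().astype(np.int64)
    if len(edges) < 2:
        return BinaryGraph(adjacency=g.adjacency.copy(), sparsity=g.sparsity)
    n_swaps = n_swaps_per_edge * len(edges)
    seed32 = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    _swap_kernel(edges, g.n_nodes, n_swaps, 100 * n_swaps, seed32)
    adj = np.zeros((g.n_nodes, g.n_nodes), dtype=np.uint8)
    adj[edges[:, 0], edges[:, 1]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


def global_metrics(
    g: BinaryGraph,
    n_null: int = 100,
    seed: int | None = None,
    n_swaps_per_edge: int = 10,
) -> GlobalMetrics:
    """The seven global measures with random-network normalization.

    Cp_rand and Lp_rand are means over ``n_null`` degree-preserving
    rewired replicates of ``g``; gamma = Cp/Cp_rand, lambda =
    Lp/Lp_rand, sigma = gamma/lambda. Lp is evaluated on the largest
    connected component; efficiencies treat disconnected pairs as
    contributing zero.
    """
    adj = np.asarray(g.adjacency)
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    cp = float(clustering_coefficient(adj).mean())
    dist = distance_matrix(adj)
    lp = _lp_largest_component(dist)
    e_glob = global_efficiency_from_dist(dist)
    e_loc = local_efficiency(adj)
    rng = np.random.default_rng(seed)
    cps, lps = np.empty(n_null), np.empty(n_null)
    base_edges = g.edge_list().astype(np.int64)
    n = g.n_nodes
    for k in range(n_null):
        edges = base_edges.copy()
        if len(edges) >= 2:
            n_swaps = n_swaps_per_edge * len(edges)
            _swap_kernel(
                edges, n, n_swaps, 100 * n_swaps, int(rng.integers(0, 2**31 - 1))
            )
        nadj = np.zeros((n, n), dtype=np.uint8)
        nadj[edges[:, 0], edges[:, 1]] = 1
        nadj |= nadj.T
        cps[k] = clustering_coefficient(nadj).mean()
        lps[k] = _lp_largest_component(distance_matrix(nadj))
    cp_rand = float(cps.mean())
    lp_rand = float(lps.mean())
    gamma = cp / cp_rand if cp_rand > 0 else np.nan
    lam = lp / lp_rand if lp_rand > 0 else np.nan
    sigma = gamma / lam if lam and np.isfinite(lam) else np.nan
    return GlobalMetrics(
        cp=cp,
        lp=lp,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        e_glob=e_glob,
        e_loc=e_loc,
        cp_rand=cp_rand,
        lp_rand=lp_rand,
    )


# ---------------------------------------------------------------------------
# AUC integration


def auc_trapezoid(grid: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over its literal grid."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.shape != values.shape:
        raise ValueError("grid and values must have matching lengths")
    if len(grid) < 2:
        raise ValueError("AUC needs at least two grid points")
    return float(np.trapezoid(values, grid))


def metric_curve(grid: SparsityGrid | np.ndarray, values: np.ndarray) -> MetricCurve:
    g = grid.values if isinstance(grid, SparsityGrid) else np.asarray(grid, float)
    values = np.asarray(values, dtype=float)
    return MetricCurve(grid=g, values=values, auc=auc_trapezoid(g, values))


def metric_curves(
    grid: SparsityGrid, per_threshold: list[dict[str, float]]
) -> dict[str, MetricCurve]:
    """Assemble per-metric curves from per-threshold metric dictionaries
    (one dict per grid point, all sharing the same keys)."""
    if len(per_threshold) != len(grid):
        raise ValueError("one metric dict per grid point required")
    names = per_threshold[0].keys()
    return {
        name: metric_curve(grid, np.array([d[name] for d in per_threshold]))
        for name in names
    }
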