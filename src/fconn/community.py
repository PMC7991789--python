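"""Modular architecture: greedy modularity optimization and module-level
metrics.

Community detection uses agglomerative greedy Q-maximization (start
from singleton communities, repeatedly merge the pair with the largest
modularity gain until no merge increases Q), with a deterministic
tie-break toward the smallest community-index pair. The healthy-control
reference partition is estimated on group occurrence graphs over a tau
grid and all subjects are then evaluated under that fixed partition, so
module-level metrics are comparable across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import distance_matrix
from .network import BinaryGraph, group_occurrence_graph

logger = logging.getLogger(__name__)


@dataclass
class ModularPartition:
    labels: np.ndarray  # node -> 0-based module id
    q: float
    module_names: list[str] | None = None
    source_tau: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (-0.5 - 1e-9 <= self.q <= 1.0 + 1e-9):
            raise ValueError(f"modularity {self.q} outside [-0.5, 1]")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


@dataclass
class ModularMetrics:
    within_degree: np.ndarray
    within_efficiency: np.ndarray
    participation: np.ndarray
    intra_conn: np.ndarray  # per module
    inter_conn: np.ndarray  # module x module, diagonal = intra
    module_ids: np.ndarray = field(default_factory=lambda: np.array([]))


def modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q = sum_s (e_ss - a_s^2) of a labeling, where
    e_ss is the fraction of edges inside module s and a_s the fraction
    of edge endpoints attached to s."""
    adj = np.asarray(adj, dtype=float)
    labels = np.asarray(labels)
    m = adj.sum() / 2
    if m == 0:
        raise ValueError("empty graph")
    q = 0.0
    for s in np.unique(labels):
        mask = labels == s
        e_ss = adj[np.ix_(mask, mask)].sum() / 2 / m
        a_s = adj[mask].sum() / (2 * m)
        q += e_ss - a_s**2
    return float(q)


def greedy_modularity(g: BinaryGraph) -> ModularPartition:
    """Agglomerative greedy Q-maximization (CNM-style merging).

    Maintains the inter-community edge-fraction matrix; at each step the
    connected community pair with the largest positive Q gain
    (dQ = e_st - 2 a_s a_t) is merged; np.argmax's row-major first-hit
    rule gives the deterministic smallest-(s, t) tie-break. Isolated
    nodes are never merged and end as singleton modules (logged).
    """
    adj = np.asarray(g.adjacency, dtype=float)
    n = g.n_nodes
    m = adj.sum() / 2
    if m == 0:
        raise ValueError("empty graph")
    n_isolated = int((adj.sum(axis=1) == 0).sum())
    if n_isolated:
        logger.info("%d isolated node(s) assigned singleton modules", n_isolated)
    # e_between[s, t]: fraction of edges between communities s and t
    e_between = adj / m
    np.fill_diagonal(e_between, 0.0)
    e_within = np.zeros(n)
    a = adj.sum(axis=1) / (2 * m)
    active = np.ones(n, dtype=bool)
    parent = np.arange(n)
    while True:
        gain = e_between - 2 * np.outer(a, a)
        gain[~active, :] = -np.inf
        gain[:, ~active] = -np.inf
        gain[e_between <= 0] = -np.inf  # merge only connected communities
        np.fill_diagonal(gain, -np.inf)
        flat = int(np.argmax(gain))
        s, t = divmod(flat, n)
        if not np.isfinite(gain[s, t]) or gain[s, t] <= 0:
            break
        s, t = min(s, t), max(s, t)
        e_within[s] += e_within[t] + e_between[s, t]
        e_between[s, :] += e_between[t, :]
        e_between[:, s] += e_between[:, t]
        e_between[s, s] = 0.0
        e_between[t, :] = 0.0
        e_between[:, t] = 0.0
        a[s] += a[t]
        a[t] = 0.0
        active[t] = False
        parent[parent == t] = s
    # compact labels preserving first-appearance order
    uniq, labels = np.unique(parent, return_inverse=True)
    q = float((e_within[active] - a[active] ** 2).sum())
    return ModularPartition(labels=labels, q=q)


def participation_coefficient(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """1 - sum_s (k_is / k_i)^2, with 0 for isolated nodes."""
    adj = np.asarray(adj, dtype=float)
    labels = np.asarray(labels)
    deg = adj.sum(axis=1)
    modules = np.unique(labels)
    onehot = np.stack([(labels == s).astype(float) for s in modules], axis=1)
    k_is = adj @ onehot  # nodes x modules
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = k_is / deg[:, None]
    frac[deg == 0] = 0.0
    p = 1.0 - (frac**2).sum(axis=1)
    p[deg == 0] = 0.0
    return p


def modular_metrics(
    g_subject: BinaryGraph,
    part: ModularPartition,
    weights: np.ndarray | None = None,
    normalization: str = "mean",
) -> ModularMetrics:
    """Module-level metrics of a subject graph under a fixed partition.

    ``within_degree`` / ``within_efficiency`` are each node's
    within-module degree / efficiency normalized by the mean over its
    module (``normalization="zscore"`` switches to the Guimera-Amaral
    z-score). ``intra_conn``/``inter_conn`` are binary edge densities,
    or mean edge weights when a symmetric ``weights`` matrix (e.g.
    Fisher z) is supplied. Single-node modules get within metrics 0 by
    convention.
    """
    if normalization not in ("mean", "zscore"):
        raise ValueError("normalization must be 'mean' or 'zscore'")
    adj = np.asarray(g_subject.adjacency, dtype=float)
    labels = part.labels
    if len(labels) != g_subject.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    modules = np.unique(labels)
    n_mod = len(modules)
    n = g_subject.n_nodes
    within_degree = np.zeros(n)
    within_eff = np.zeros(n)
    intra = np.zeros(n_mod)
    inter = np.zeros((n_mod, n_mod))
    wmat = np.asarray(weights, dtype=float) if weights is not None else None
    for si, s in enumerate(modules):
        mask = labels == s
        idx = np.nonzero(mask)[0]
        sub = adj[np.ix_(idx, idx)]
        n_s = len(idx)
        if n_s == 1:
            logger.info("module %d has a single node; within metrics set to 0", s)
            intra[si] = 0.0
            continue
        wdeg = sub.sum(axis=1)
        subdist = distance_matrix(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / subdist
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        weff = inv.sum(axis=1) / (n_s - 1)
        for raw, out in ((wdeg, within_degree), (weff, within_eff)):
            if normalization == "mean":
                mu = raw.mean()
                out[idx] = raw / mu if mu > 0 else 0.0
            else:
                mu, sd = raw.mean(), raw.std()
                out[idx] = (raw - mu) / sd if sd > 0 else 0.0
        if wmat is not None:
            iu = np.triu_indices(n_s, 1)
            intra[si] = float(wmat[np.ix_(idx, idx)][iu].mean())
        else:
            intra[si] = float(sub.sum() / (n_s * (n_s - 1)))
    for si, s in enumerate(modules):
        for ti in range(si + 1, n_mod):
            t = modules[ti]
            a_idx = np.nonzero(labels == s)[0]
            b_idx = np.nonzero(labels == t)[0]
            block = (wmat if wmat is not None else adj)[np.ix_(a_idx, b_idx)]
            inter[si, ti] = inter[ti, si] = float(block.mean())
    np.fill_diagonal(inter, intra)
    return ModularMetrics(
        within_degree=within_degree,
        within_efficiency=within_eff,
        participation=participation_coefficient(adj, labels),
        intra_conn=intra,
        inter_conn=inter,
        module_ids=modules,
    )


def name_modules(
    part: ModularPartition, reference_labels: np.ndarray, reference_names: list[str]
) -> list[str]:
    """Name each detected module by its majority overlap with a reference
    parcellation (e.g. the atlas module table)."""
    names = []
    ref = np.asarray(reference_labels)
    for s in np.unique(part.labels):
        members = part.labels == s
        overlap = ref[members]
        vals, counts = np.unique(overlap, return_counts=True)
        names.append(reference_names[int(vals[np.argmax(counts)])])
    return names


def hc_reference_partitions(
    hc_graphs: list[BinaryGraph],
    taus: np.ndarray | None = None,
    atlas_labels: np.ndarray | None = None,
    atlas_names: list[str] | None = None,
) -> list[ModularPartition]:
    """Greedy-modularity partitions of HC occurrence graphs over the tau
    grid (default 0.50..0.70 step 0.01). Taus yielding edgeless graphs
    are skipped with a warning."""
    if taus is None:
        taus = np.round(np.arange(0.50, 0.701, 0.01), 2)
    parts: list[ModularPartition] = []
    for tau in taus:
        g = group_occurrence_graph(hc_graphs, float(tau))
        if g.n_edges == 0:
            logger.warning("tau=%.2f yields an edgeless occurrence graph; skipped", tau)
            continue
        part = greedy_modularity(g)
        part.source_tau = float(tau)
        if atlas_labels is not None and atlas_names is not None:
            part.module_names = name_modules(part, atlas_labels, atlas_names)
        parts.append(part)
    return parts


def best_partition(parts: list[ModularPartition]) -> ModularPartition:
    """The reporting partition: maximal Q (ties toward the smaller tau)."""
    if not parts:
        raise ValueError("no partitions supplied")
    return max(parts, key=lambda p: (p.q, -(p.source_tau or 0.0)))
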