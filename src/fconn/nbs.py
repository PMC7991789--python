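"""Network-based statistic (NBS) for three-group connectome comparisons.

Edgewise one-way ANOVA F statistics are computed across groups on
Fisher-z connectivity values (optionally residualized for age/gender);
edges exceeding a primary cluster-defining threshold (default F = 12)
form a suprathreshold graph whose connected components are the
candidate effects. Family-wise error over components is controlled by a
permutation null of the maximal component size (in edges): group labels
are globally shuffled, the edgewise pipeline repeated, and each
observed component assigned p = (b + 1) / (m + 1), the fraction of
permutations (plus the observed labeling) whose maximal component is at
least as large. Post hoc two-sample t-tests characterise the pairwise
differences on edges inside significant components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class NbsComponent:
    edges: np.ndarray  # k x 2 node-index pairs
    nodes: np.ndarray
    size: int  # edge count
    p_corrected: float = np.nan


@dataclass
class NbsResult:
    f_matrix: np.ndarray
    primary_f: float
    components: list[NbsComponent]
    null_sizes: np.ndarray
    n_perm: int
    posthoc: dict = field(default_factory=dict)

    @property
    def significant(self) -> list[NbsComponent]:
        return [c for c in self.components if c.p_corrected < 0.05]


def _group_indicator(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, gidx = np.unique(groups, return_inverse=True)
    return levels, gidx


def edgewise_f(values: np.ndarray, gidx: np.ndarray, n_levels: int) -> np.ndarray:
    """Vectorized one-way ANOVA F across the columns of a subjects x
    edges matrix."""
    n, _ = values.shape
    onehot = np.zeros((n_levels, n))
    onehot[gidx, np.arange(n)] = 1.0
    counts = onehot.sum(axis=1)
    sums = onehot @ values
    means = sums / counts[:, None]
    grand = values.mean(axis=0)
    ss_between = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_total = ((values - grand) ** 2).sum(axis=0)
    ss_within = ss_total - ss_between
    df_b = n_levels - 1
    df_w = n - n_levels
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.where(np.isfinite(f), f, 0.0)


def components_from_mask(
    edge_mask: np.ndarray, iu: tuple[np.ndarray, np.ndarray], n_nodes: int
) -> list[NbsComponent]:
    """Connected components of the suprathreshold edge graph, sorted by
    decreasing edge count."""
    sel = np.nonzero(edge_mask)[0]
    if sel.size == 0:
        return []
    i, j = iu[0][sel], iu[1][sel]
    a = coo_matrix((np.ones(sel.size), (i, j)), shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(a + a.T, directed=False)
    comps: list[NbsComponent] = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        if len(members) < 2:
            continue
        in_comp = np.isin(i, members)
        if not in_comp.any():
            continue
        edges = np.stack([i[in_comp], j[in_comp]], axis=1)
        comps.append(NbsComponent(edges=edges, nodes=members, size=int(in_comp.sum())))
    comps.sort(key=lambda c: -c.size)
    return comps


def _max_component_size(
    edge_mask: np.ndarray, iu: tuple[np.ndarray, np.ndarray], n_nodes: int
) -> int:
    sel = np.nonzero(edge_mask)[0]
    if sel.size == 0:
        return 0
    i, j = iu[0][sel], iu[1][sel]
    a = coo_matrix((np.ones(sel.size), (i, j)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(a + a.T, directed=False)
    edge_labels = labels[i]
    return int(np.bincount(edge_labels).max())


def _residualize_matrix(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(values)), covariates])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def nbs_anova(
    z_matrices: np.ndarray,
    groups: np.ndarray,
    primary_f: float = 12.0,
    n_perm: int = 10000,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
    perm_block: int = 500,
) -> NbsResult:
    """Run the NBS omnibus test on a subjects x nodes x nodes z stack.

    ``covariates`` (e.g. age and coded gender, subjects x q) are
    residualized out of the edge values before both the observed and
    every permuted F computation, keeping the NBS inputs consistent
    with the metric pipeline.
    """
    z_matrices = np.asarray(z_matrices, dtype=float)
    groups = np.asarray(groups)
    if primary_f <= 0:
        raise ValueError("primary_f must be positive")
    s, n_nodes, _ = z_matrices.shape
    levels, gidx = _group_indicator(groups)
    if len(levels) < 2 or np.bincount(gidx).min() < 2:
        raise ValueError("need at least 2 subjects in each of at least 2 groups")
    iu = np.triu_indices(n_nodes, 1)
    values = z_matrices[:, iu[0], iu[1]]
    if covariates is not None:
        values = _residualize_matrix(values, np.asarray(covariates, dtype=float))
    f_obs = edgewise_f(values, gidx, len(levels))
    comps = components_from_mask(f_obs > primary_f, iu, n_nodes)
    rng = np.random.default_rng(seed)
    null_sizes = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        block = min(perm_block, n_perm - done)
        perms = np.stack([rng.permutation(gidx) for _ in range(block)])
        f_null = _edgewise_f_block(values, perms, len(levels))
        over = f_null > primary_f
        for b in range(block):
            null_sizes[done + b] = (
                _max_component_size(over[b], iu, n_nodes) if over[b].any() else 0
            )
        done += block
    for comp in comps:
        comp.p_corrected = (1 + int((null_sizes >= comp.size).sum())) / (n_perm + 1)
    f_matrix = np.zeros((n_nodes, n_nodes))
    f_matrix[iu] = f_obs
    f_matrix += f_matrix.T
    result = NbsResult(
        f_matrix=f_matrix,
        primary_f=primary_f,
        components=comps,
        null_sizes=null_sizes,
        n_perm=n_perm,
    )
    if result.significant:
        result.posthoc = posthoc_edges(result, z_matrices, groups, covariates=covariates)
    return result


def _edgewise_f_block(
    values: np.ndarray, perms: np.ndarray, n_levels: int
) -> np.ndarray:
    """F statistics for a block of permuted labelings (block x edges)."""
    n, n_edges = values.shape
    block = perms.shape[0]
    grand = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum(axis=0)
    df_b = n_levels - 1
    df_w = n - n_levels
    ss_between = np.zeros((block, n_edges))
    counts = np.stack([(perms == g).sum(axis=1) for g in range(n_levels)], axis=1)
    for g in range(n_levels):
        ind = (perms == g).astype(float)  # block x subjects
        sums = ind @ values  # block x edges
        means = sums / counts[:, g][:, None]
        ss_between += counts[:, g][:, None] * (means - grand) ** 2
    ss_within = ss_total[None, :] - ss_between
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.where(np.isfinite(f), f, 0.0)


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and two-sided p."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


def posthoc_edges(
    result: NbsResult,
    z_matrices: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    welch: bool = False,
) -> dict:
    """Pairwise two-sample t-tests per edge within significant components.

    Returns ``{(group_a, group_b): [(i, j, t, p), ...]}``; pooled
    variance by default, Welch on request.
    """
    sig = result.significant
    if not sig:
        raise ValueError("no significant component to follow up")
    z_matrices = np.asarray(z_matrices, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    n_nodes = z_matrices.shape[1]
    if covariates is not None:
        iu = np.triu_indices(n_nodes, 1)
        vals = _residualize_matrix(
            z_matrices[:, iu[0], iu[1]], np.asarray(covariates, dtype=float)
        )
        full = np.zeros_like(z_matrices)
        full[:, iu[0], iu[1]] = vals
        full[:, iu[1], iu[0]] = vals
        z_matrices = full
    out: dict = {}
    for ai in range(len(levels)):
        for bi in range(ai + 1, len(levels)):
            a, b = levels[ai], levels[bi]
            rows = []
            for comp in sig:
                for i, j in comp.edges:
                    x = z_matrices[groups == a, i, j]
                    y = z_matrices[groups == b, i, j]
                    if welch:
                        t, p = sps.ttest_ind(x, y, equal_var=False)
                        t, p = float(t), float(p)
                    else:
                        t, p = pooled_t(x, y)
                    rows.append((int(i), int(j), t, p))
            out[(str(a), str(b))] = rows
    return out
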