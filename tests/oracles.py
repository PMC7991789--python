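"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive pure Python (adjacency lists,
queue-based BFS, explicit triangle enumeration, literal definition
formulas) and shares no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def adjlist(adj: np.ndarray) -> list[list[int]]:
    n = len(adj)
    return [[j for j in range(n) if adj[i][j]] for i in range(n)]


def bfs_distances(neigh: list[list[int]], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in neigh[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_pairs(adj: np.ndarray) -> list[dict[int, int]]:
    neigh = adjlist(adj)
    return [bfs_distances(neigh, s) for s in range(len(adj))]


def oracle_clustering(adj: np.ndarray) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a]][nbrs[b]]:
                    links += 1
        out.append(2 * links / (k * (k - 1)))
    return out


def oracle_lp_largest_component(adj: np.ndarray) -> float:
    """Mean shortest path over pairs of the largest connected component."""
    n = len(adj)
    dists = all_pairs(adj)
    comps: list[set[int]] = []
    seen: set[int] = set()
    for s in range(n):
        if s in seen:
            continue
        comp = set(dists[s])
        comps.append(comp)
        seen |= comp
    largest = max(comps, key=len)
    if len(largest) < 2:
        return 0.0
    total, count = 0, 0
    for i in largest:
        for j in largest:
            if i != j:
                total += dists[i][j]
                count += 1
    return total / count


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    if n < 2:
        return 0.0
    dists = all_pairs(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and j in dists[i]:
                total += 1.0 / dists[i][j]
    return total / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(oracle_global_efficiency(sub))
    return float(np.mean(vals))


def oracle_nodal_efficiency(adj: np.ndarray) -> list[float]:
    n = len(adj)
    dists = all_pairs(adj)
    out = []
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and j in dists[i]:
                s += 1.0 / dists[i][j]
        out.append(s / (n - 1))
    return out


def oracle_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    n = len(adj)
    m = int(adj.sum()) // 2
    q = 0.0
    for s in set(int(x) for x in labels):
        inside = 0
        ends = 0
        for i in range(n):
            if labels[i] != s:
                continue
            for j in range(n):
                if adj[i][j]:
                    ends += 1
                    if labels[j] == s and i < j:
                        inside += 1
        q += inside / m - (ends / (2 * m)) ** 2
    return q


def oracle_participation(adj: np.ndarray, labels: np.ndarray) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        k = int(adj[i].sum())
        if k == 0:
            out.append(0.0)
            continue
        acc = 0.0
        for s in set(int(x) for x in labels):
            k_is = sum(adj[i][j] for j in range(n) if labels[j] == s)
            acc += (k_is / k) ** 2
        out.append(1.0 - acc)
    return out


def union_find_components(edges: list[tuple[int, int]]) -> list[set[int]]:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return list(groups.values())


def oracle_anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    levels = sorted(set(groups.tolist()))
    grand = float(np.mean(values))
    ss_b = ss_w = 0.0
    for g in levels:
        v = values[groups == g]
        ss_b += len(v) * (float(v.mean()) - grand) ** 2
        ss_w += float(((v - v.mean()) ** 2).sum())
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    return (ss_b / df_b) / (ss_w / df_w)


def oracle_chi2(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def oracle_pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def oracle_adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """ARI from the contingency table via the closed-form formula."""
    from math import comb

    la, lb = sorted(set(a.tolist())), sorted(set(b.tolist()))
    table = np.array([[int(((a == x) & (b == y)).sum()) for y in lb] for x in la])
    sum_comb = sum(comb(int(nij), 2) for nij in table.ravel())
    sum_a = sum(comb(int(n), 2) for n in table.sum(axis=1))
    sum_b = sum(comb(int(n), 2) for n in table.sum(axis=0))
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


def oracle_partial_corr_invcov(data: np.ndarray, xi: int, yi: int) -> float:
    """Partial correlation of columns xi, yi controlling for all other
    columns, via the inverse correlation matrix."""
    r = np.corrcoef(data, rowvar=False)
    p = np.linalg.inv(r)
    return float(-p[xi, yi] / np.sqrt(p[xi, xi] * p[yi, yi]))
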