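"""Psychometric subtyping of patients.

Patients are clustered on their normalized anxiety/depression scores
(SDS, SAS, SAI, TAI) by Ward hierarchical clustering on Euclidean
distances; the number of clusters is chosen by majority vote of the
silhouette coefficient (max), Calinski-Harabasz index (max) and
Davies-Bouldin index (min) over a candidate range, with ties broken
toward fewer clusters. For the two-cluster solution the cluster with
the higher mean normalized score is named FCAD (the
anxiety/depression-associated subtype) and the other FCNAD. The
partition is retested for stability against PAM k-medoids and fuzzy
C-means via the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

SCALE_COLUMNS = ("sds", "sas", "sai", "tai")

#: Silhouette below this at the selected k flags weak cluster structure.
WEAK_SILHOUETTE = 0.4


@dataclass
class ClusterSolution:
    labels: np.ndarray  # 1..k cluster ids
    k: int
    indices: dict[int, dict[str, float]]  # per candidate k
    linkage_record: np.ndarray
    method: str
    subtype_names: np.ndarray | None = None  # FCAD/FCNAD when k == 2
    votes: dict[str, int] = field(default_factory=dict)
    weak_structure: bool = False


def normalize_scores(scores: np.ndarray, method: str = "zscore") -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if method == "zscore":
        sd = scores.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (scores - scores.mean(axis=0)) / sd
    if method == "minmax":
        lo, hi = scores.min(axis=0), scores.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        return (scores - lo) / rng
    raise ValueError("method must be 'zscore' or 'minmax'")


def validity_indices(x: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    return {
        "silhouette": float(silhouette_score(x, labels)),
        "calinski_harabasz": float(calinski_harabasz_score(x, labels)),
        "davies_bouldin": float(davies_bouldin_score(x, labels)),
    }


def _vote(indices: dict[int, dict[str, float]]) -> tuple[int, dict[str, int]]:
    ks = sorted(indices)
    votes = {
        "silhouette": max(ks, key=lambda k: (indices[k]["silhouette"], -k)),
        "calinski_harabasz": max(ks, key=lambda k: (indices[k]["calinski_harabasz"], -k)),
        "davies_bouldin": min(ks, key=lambda k: (indices[k]["davies_bouldin"], k)),
    }
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    winner = min(k for k, c in counts.items() if c == best)
    return winner, votes


def subtype_patients(
    scores: np.ndarray,
    k_range: range = range(2, 7),
    normalization: str = "zscore",
) -> ClusterSolution:
    """Ward clustering of a patients x 4 score matrix with
    cluster-number selection by index majority vote."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("missing scores")
    if scores.shape[0] <= max(k_range):
        raise ValueError("need more patients than the largest candidate k")
    x = normalize_scores(scores, normalization)
    link = linkage(x, method="ward", metric="euclidean")
    cuts = {k: fcluster(link, t=k, criterion="maxclust") for k in k_range}
    indices = {k: validity_indices(x, cuts[k]) for k in k_range}
    k_best, votes = _vote(indices)
    labels = cuts[k_best]
    names = None
    if k_best == 2:
        means = [x[labels == c].mean() for c in (1, 2)]
        high = 1 + int(np.argmax(means))
        names = np.where(labels == high, "FCAD", "FCNAD")
    return ClusterSolution(
        labels=labels,
        k=k_best,
        indices=indices,
        linkage_record=link,
        method="ward",
        subtype_names=names,
        votes=votes,
        weak_structure=indices[k_best]["silhouette"] < WEAK_SILHOUETTE,
    )


# ---------------------------------------------------------------------------
# retest algorithms


def kmedoids(
    x: np.ndarray, k: int, seed: int | None = None, max_iter: int = 200
) -> np.ndarray:
    """PAM k-medoids (random init, greedy swap phase) on Euclidean
    distances; returns 1..k labels."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = cdist(x, x)
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    cost = d[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = np.setdiff1d(np.arange(n), medoids)
            trial = medoids.copy()
            # best single replacement for this medoid
            costs = np.empty(len(others))
            for oi, o in enumerate(others):
                trial[mi] = o
                costs[oi] = d[:, trial].min(axis=1).sum()
            best = int(np.argmin(costs))
            if costs[best] < cost - 1e-12:
                medoids[mi] = others[best]
                cost = costs[best]
                improved = True
        if not improved:
            break
    return np.argmin(d[:, medoids], axis=1) + 1


def fuzzy_cmeans(
    x: np.ndarray,
    k: int,
    m: float = 2.0,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fuzzy C-means with fuzzifier ``m``; returns (hard labels 1..k,
    membership matrix, converged flag). Hard labels defuzzify by maximal
    membership."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=n)  # n x k memberships
    converged = False
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        dist = cdist(x, centers)
        dist = np.maximum(dist, 1e-12)
        inv = dist ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            converged = True
            break
        u = u_new
    return np.argmax(u, axis=1) + 1, u, converged


@dataclass
class ConcordanceReport:
    ari_kmedoids: float
    ari_fuzzy_cmeans: float
    fcm_converged: bool


def retest_concordance(
    scores: np.ndarray,
    reference_labels: np.ndarray,
    k: int,
    seed: int | None = None,
    normalization: str = "zscore",
) -> ConcordanceReport:
    """Adjusted Rand agreement of PAM k-medoids and fuzzy C-means
    partitions with the Ward reference labels at fixed k."""
    x = normalize_scores(np.asarray(scores, dtype=float), normalization)
    rng = np.random.default_rng(seed)
    km = kmedoids(x, k, seed=int(rng.integers(2**31 - 1)))
    fcm, _, converged = fuzzy_cmeans(x, k, seed=int(rng.integers(2**31 - 1)))
    return ConcordanceReport(
        ari_kmedoids=float(adjusted_rand_score(reference_labels, km)),
        ari_fuzzy_cmeans=float(adjusted_rand_score(reference_labels, fcm)),
        fcm_converged=converged,
    )
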