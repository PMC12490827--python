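"""k-medoids clustering of molecules with an iterative cluster-size floor.

Molecules are compared by Euclidean distance over their smoothed in-window
protection features and partitioned with the classic Kaufman–Rousseeuw
PAM algorithm (greedy BUILD followed by best-improvement SWAP). The
requested number of clusters k (default 16) is reduced one step at a time
until every cluster holds at least ``min_cluster_size`` molecules (default
5), which caps the number of reported occupancy patterns and absorbs
technical noise into larger clusters.

Everything here is deterministic: ties in BUILD, SWAP and assignment are
broken by the lowest molecule index, so identical inputs always yield
identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import SmoothedMatrix

DEFAULT_K = 16
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass
class ClusterResult:
    """Partition of molecules into clusters with their medoids.

    Cluster ids are 1..k_final, ordered by medoid molecule index.
    ``low_coverage`` flags the degenerate single-cluster result returned
    when fewer than ``min_cluster_size`` molecules were available.
    """

    assignments: np.ndarray  # int, cluster id in 1..k_final per molecule
    medoids: np.ndarray  # molecule indices, one per cluster
    k_requested: int
    k_final: int
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    low_coverage: bool = False
    total_cost: float = 0.0

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k_final + 1)[1:]

    def molecules_in(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)


def pairwise_distances(features: SmoothedMatrix) -> np.ndarray:
    """Missing-rescaled Euclidean distances over in-window features.

    For molecules i, j sharing observed in-window positions S out of P
    total, d(i,j) = sqrt((P/|S|) * sum_{p in S} (x_ip - x_jp)^2); with no
    shared position, d is set to the largest finite distance in the matrix
    plus one. Fully observed rows reduce to plain Euclidean distance.
    """
    mask = features.in_window
    X = features.values[:, mask]
    n, P = X.shape
    if n < 2:
        raise ValueError("need at least 2 molecules to compute distances")
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("every molecule must have at least one in-window feature")
    X0 = np.where(obs, X, 0.0)
    # pairwise sums over shared positions, treating NaN as 0 then correcting
    shared = obs.astype(np.float64) @ obs.T  # |S| per pair
    sq = X0**2
    cross = X0 @ X0.T
    # sum over shared of x_i^2: positions observed in both
    sum_sq_i = sq @ obs.T
    ssd = sum_sq_i + sum_sq_i.T - 2 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.maximum(ssd, 0.0) * (P / shared))
    np.fill_diagonal(d, 0.0)
    no_shared = shared == 0
    if no_shared.any():
        finite = d[~no_shared]
        fill = (finite[np.isfinite(finite)].max() if np.isfinite(finite).any() else 0.0) + 1.0
        d[no_shared] = fill
        np.fill_diagonal(d, 0.0)
    return d


def _assign(dist: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid index (into ``medoids``); ties go to the lowest medoid index."""
    sub = dist[:, medoids]  # medoids assumed sorted ascending
    return np.argmin(sub, axis=1)


def pam(dist: np.ndarray, k: int) -> ClusterResult:
    """Classic PAM (BUILD + SWAP) on a precomputed distance matrix.

    BUILD greedily adds the medoid giving the largest decrease in total
    cost (sum over molecules of the distance to the nearest medoid); SWAP
    repeatedly applies the single best medoid/non-medoid exchange while it
    strictly decreases the cost. No randomness anywhere.
    """
    n = dist.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")

    # BUILD: first medoid minimises total distance; ties -> lowest index
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum over points of max(0, nearest - d(.,c))
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))  # argmax returns the lowest index on ties
        medoids.append(c)
        nearest = np.minimum(nearest, dist[:, c])

    medoid_set = sorted(medoids)
    cost = _total_cost(dist, medoid_set)
    while True:
        best_delta = 0.0
        best_swap = None
        non_medoids = [h for h in range(n) if h not in medoid_set]
        for mi, m in enumerate(medoid_set):
            others = medoid_set[:mi] + medoid_set[mi + 1 :]
            if others:
                d_others = dist[:, others].min(axis=1)
            else:
                d_others = np.full(n, np.inf)
            for h in non_medoids:
                new_nearest = np.minimum(d_others, dist[:, h])
                delta = new_nearest.sum() - cost
                if delta < best_delta - 1e-12:
                    best_delta = delta
                    best_swap = (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoid_set[mi] = h
        medoid_set = sorted(medoid_set)
        cost += best_delta
        cost = _total_cost(dist, medoid_set)  # re-derive to avoid drift

    medoid_arr = np.asarray(medoid_set, dtype=np.int64)
    idx = _assign(dist, medoid_arr)
    return ClusterResult(
        assignments=idx + 1,
        medoids=medoid_arr,
        k_requested=k,
        k_final=k,
        total_cost=cost,
    )


def _total_cost(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def cluster_with_size_floor(
    dist: np.ndarray,
    k_init: int = DEFAULT_K,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> ClusterResult:
    """Run PAM, decrementing k until every cluster meets the size floor.

    Starts at ``min(k_init, n_molecules)``; whenever some cluster holds
    fewer than ``min_cluster_size`` molecules and k > 1, k is reduced by
    one and PAM re-run from scratch. With fewer molecules than the floor,
    a single flagged cluster is returned instead of an error so that
    sparse windows survive multi-region runs.
    """
    if k_init < 1 or min_cluster_size < 1:
        raise ValueError("k_init and min_cluster_size must be >= 1")
    n = dist.shape[0]
    if n < min_cluster_size:
        result = pam(dist, 1)
        result.k_requested = k_init
        result.min_cluster_size = min_cluster_size
        result.low_coverage = True
        return result
    k = min(k_init, n)
    while True:
        result = pam(dist, k)
        result.k_requested = k_init
        result.min_cluster_size = min_cluster_size
        if k == 1 or (result.cluster_sizes >= min_cluster_size).all():
            return result
        k -= 1
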