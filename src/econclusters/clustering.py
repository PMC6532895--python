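"""Weighted k-medoids (PAM) and the weighted average silhouette width.

This is the numerical core of the method.  Classic BUILD+SWAP PAM is
implemented directly on a precomputed dissimilarity matrix with positive
case weights (here: summed survey weights of the households sharing an
asset profile), with deterministic multi-start: BUILD is seeded once from
every profile as the forced first medoid, duplicate seed sets are
collapsed, SWAP is run to convergence from each distinct seed, and the
lowest-cost solution wins.  Single-start SWAP is a local search and can
stall a few percent of the time on small instances; the all-starts variant
restores the exhaustive-search behaviour the model selection relies on
while remaining a polynomial local search on large profile sets.  Profile
aggregation keeps instances small, so the extra starts stay cheap.

Determinism rules (fixed, so results never depend on execution order):

* BUILD ties go to the lowest profile index.
* SWAP applies the single best-improving (medoid, non-medoid) exchange per
  iteration and only accepts strict cost decreases; equal-cost swaps are
  rejected.
* Equal-cost final solutions resolve to the lexicographically smallest
  sorted medoid set.
* Nearest-medoid label ties go to the lowest medoid index.

The weighted silhouette treats weights as replicate counts: for profile
``i`` in cluster ``C`` with cluster weight ``W_C``,

    a_i = sum_{j in C} w_j d(i, j) / (W_C - 1)
    b_i = min_{C' != C} sum_{j in C'} w_j d(i, j) / W_{C'}
    s_i = (b_i - a_i) / max(a_i, b_i)

with ``s_i = 0`` when ``W_C <= 1`` (an effectively-singleton case) or when
``max(a_i, b_i) = 0``; the ASW is the w-weighted mean of the ``s_i``.  With
integer weights this agrees exactly with the unweighted silhouette on the
matrix in which every profile is replicated ``w_i`` times, and with unit
weights it is the textbook silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import EconClustersError


@dataclass
class PamResult:
    medoid_indices: np.ndarray  # sorted, K distinct profile indices
    labels: np.ndarray          # profile -> cluster 0..K-1 (index into medoid_indices)
    total_cost: float           # sum_i w_i d(i, medoid(i))


@dataclass
class SilhouetteReport:
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    asw: float


def _check_inputs(d: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise EconClustersError("dissimilarity matrix must be square")
    if len(weights) != d.shape[0]:
        raise EconClustersError("weights length must match matrix order")
    if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
        raise EconClustersError("weights must be positive and finite")
    return d, weights


def _build(d: np.ndarray, w: np.ndarray, k: int, first: int) -> tuple[int, ...]:
    """Greedy BUILD seeding with a forced first medoid."""
    medoids = [first]
    dmin = d[:, first].copy()
    while len(medoids) < k:
        # weighted cost reduction from adding each candidate column
        reduction = w @ np.maximum(dmin[:, None] - d, 0.0)
        reduction[medoids] = -np.inf
        c = int(np.argmax(reduction))
        medoids.append(c)
        dmin = np.minimum(dmin, d[:, c])
    return tuple(sorted(medoids))


def _swap(d: np.ndarray, w: np.ndarray, seed: tuple[int, ...]) -> tuple[float, tuple[int, ...]]:
    """Best-improvement SWAP local search from a medoid set."""
    n = d.shape[0]
    medoids = list(seed)
    current = float(w @ d[:, medoids].min(axis=1))
    while True:
        best_cost = current
        best_swap = None
        med_set = set(medoids)
        non = [h for h in range(n) if h not in med_set]
        if not non:
            break
        d_non = d[:, non]
        for m in medoids:
            others = [x for x in medoids if x != m]
            d_others = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            cand_costs = w @ np.minimum(d_others[:, None], d_non)
            j = int(np.argmin(cand_costs))
            if cand_costs[j] < best_cost:
                best_cost = float(cand_costs[j])
                best_swap = (m, non[j])
        if best_swap is None:
            break
        medoids = sorted(set(medoids) - {best_swap[0]} | {best_swap[1]})
        current = best_cost
    return current, tuple(medoids)


def weighted_pam(d: np.ndarray, weights: np.ndarray, k: int) -> PamResult:
    """Weighted PAM (multi-start BUILD+SWAP) on a dissimilarity matrix.

    BUILD greedily seeds ``k`` medoids with each profile in turn forced as
    the first medoid; SWAP runs the best strictly-improving exchange to
    convergence from every distinct seed set, and the lowest-cost solution
    (ties to the lexicographically smallest medoid set) is returned.  The
    result is deterministic and independent of evaluation order.
    """
    d, w = _check_inputs(d, weights)
    n = d.shape[0]
    if not (1 <= k <= n):
        raise EconClustersError(f"k={k} out of range for {n} profiles")

    seeds = {_build(d, w, k, first) for first in range(n)}
    best_cost = np.inf
    best_medoids: tuple[int, ...] | None = None
    for seed in sorted(seeds):
        cost, medoids = _swap(d, w, seed)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and medoids < best_medoids
        ):
            best_cost = cost
            best_medoids = medoids

    medoid_arr = np.array(best_medoids, dtype=int)
    labels = np.argmin(d[:, medoid_arr], axis=1)  # first minimum = lowest medoid index
    total_cost = float(w @ d[medoid_arr[labels], np.arange(n)])
    return PamResult(medoid_indices=medoid_arr, labels=labels, total_cost=total_cost)


def weighted_asw(d: np.ndarray, weights: np.ndarray, labels: np.ndarray) -> SilhouetteReport:
    """Weighted silhouette widths and their weighted mean (the ASW)."""
    d, w = _check_inputs(d, weights)
    labels = np.asarray(labels)
    clusters, idx = np.unique(labels, return_inverse=True)
    n_clusters = len(clusters)
    if n_clusters < 2:
        raise EconClustersError("silhouette needs at least two non-empty clusters")

    onehot = np.zeros((len(labels), n_clusters))
    onehot[np.arange(len(labels)), idx] = 1.0
    cluster_w = w @ onehot
    if np.any(cluster_w <= 0):
        raise EconClustersError("cluster with non-positive total weight")

    # S[i, c] = sum over j in cluster c of w_j * d(i, j)
    S = d @ (onehot * w[:, None])
    own_w = cluster_w[idx]
    own_S = S[np.arange(len(labels)), idx]

    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(own_w > 1.0, own_S / (own_w - 1.0), 0.0)
    mean_other = S / cluster_w[None, :]
    mean_other[np.arange(len(labels)), idx] = np.inf
    b = mean_other.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(len(labels))
    ok = (denom > 0) & (own_w > 1.0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    asw = float((w * s).sum() / w.sum())
    return SilhouetteReport(a=a, b=b, s=s, asw=asw)
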