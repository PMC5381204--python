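"""Decoy clustering: K-means over a distance matrix, SPICKER-style
one-step clustering, the SPICKER-seeded hybrid (SK-means), and
K-means++ seeding.

All methods operate on a precomputed :class:`~decoyclust.metrics.DistanceMatrix`
rather than raw coordinates.  Cluster centers are therefore *medoids* —
actual ensemble members minimizing total within-cluster distance — never
coordinate averages: averaging conformations without mutual superposition
produces nonphysical chains, and a medoid is well defined for any
dissimilarity, including ``1 - TM``.

Determinism contract: every operation is a pure function of its inputs and
the seed of the generator it is handed.  Ties are always broken toward the
lowest member index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .metrics import DistanceMatrix

__all__ = [
    "Clustering",
    "SpickerParams",
    "medoid",
    "assign_to_nearest",
    "clustering_objective",
    "kmeans",
    "kmeans_pp_seed",
    "spicker_cluster",
    "sk_means",
    "kmeans_plusplus",
    "select_models",
]

logger = logging.getLogger(__name__)


@dataclass
class Clustering:
    """A partition of ensemble members into K medoid-centered clusters."""

    assignment: np.ndarray          # length N, values in [0, K)
    center_indices: np.ndarray      # length K member indices (medoids)
    n_iterations: int
    metric: str = "rmsd"
    seed_method: str = "random"

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.center_indices = np.asarray(self.center_indices, dtype=int)
        K = len(self.center_indices)
        if len(np.unique(self.center_indices)) != K:
            raise ValueError("cluster centers must be distinct members")
        if self.assignment.min() < 0 or self.assignment.max() >= K:
            raise ValueError("assignment refers to a nonexistent cluster")
        for k, c in enumerate(self.center_indices):
            if self.assignment[c] != k:
                raise ValueError(f"center {c} is not assigned to its own cluster {k}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def k(self) -> int:
        return len(self.center_indices)

    def members_of(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


@dataclass(frozen=True)
class SpickerParams:
    """Knobs of the SPICKER-style one-step clustering.

    The pairwise-RMSD cutoff starts at ``initial_cutoff`` and is adjusted
    multiplicatively (10% per step) until the largest neighborhood holds a
    fraction of the ensemble inside ``target_fraction_range``, clamped to
    ``[cutoff_min, cutoff_max]``.  Ensembles larger than
    ``representative_cap`` are thinned to an evenly strided subset first.
    """

    initial_cutoff: float = 8.0
    cutoff_min: float = 3.5
    cutoff_max: float = 12.0
    target_fraction_range: tuple = (0.15, 0.70)
    max_adjust_iterations: int = 20
    max_clusters: int = 5
    representative_cap: int = 13000

    def __post_init__(self) -> None:
        lo, hi = self.target_fraction_range
        if not (self.cutoff_min <= self.initial_cutoff <= self.cutoff_max):
            raise ValueError("cutoff_min <= initial_cutoff <= cutoff_max required")
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("target_fraction_range must satisfy 0 < low < high < 1")


def medoid(D: DistanceMatrix, members: Sequence[int]) -> int:
    """Member of ``members`` minimizing total distance to the others.

    Ties are broken toward the lowest member index.
    """
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("medoid of an empty member set is undefined")
    sub = D.values[np.ix_(members, members)]
    totals = sub.sum(axis=1)
    return int(members[int(np.argmin(totals))])  # argmin takes the first minimum


def assign_to_nearest(D: DistanceMatrix, center_indices: Sequence[int]) -> np.ndarray:
    """Assign every member to its nearest center (ties to the earlier center).

    A center is always assigned to itself (its self-distance is zero).
    """
    centers = np.asarray(list(center_indices), dtype=int)
    if len(np.unique(centers)) != len(centers):
        raise ValueError("centers must be distinct")
    dists = D.values[:, centers]  # N x K
    assignment = np.argmin(dists, axis=1)
    # a center belongs to its own cluster even when another center sits at
    # distance zero and would win the lowest-index tie
    assignment[centers] = np.arange(len(centers))
    return assignment


def clustering_objective(D: DistanceMatrix, assignment: np.ndarray,
                         center_indices: np.ndarray) -> float:
    """Sum over members of the distance to their cluster's center."""
    return float(D.values[np.arange(D.n), np.asarray(center_indices)[assignment]].sum())


def _repair_empty_clusters(D: DistanceMatrix, assignment: np.ndarray,
                           centers: np.ndarray) -> None:
    """Give each empty cluster the member farthest from its current center.

    Deterministic: the globally farthest non-center member is seized first;
    ties break toward the lower index.  Modifies ``assignment``/``centers``
    in place.
    """
    K = len(centers)
    for k in range(K):
        if np.any(assignment == k):
            continue
        resid = D.values[np.arange(D.n), centers[assignment]].copy()
        resid[centers] = -1.0  # never seize a center
        far = int(np.argmax(resid))
        assignment[far] = k
        centers[k] = far


def kmeans(D: DistanceMatrix, initial_centers: Sequence[int],
           max_iter: int = 100, rng: Optional[np.random.Generator] = None,
           seed_method: str = "random") -> Clustering:
    """Lloyd-style K-means over a distance matrix with medoid centers.

    Alternates nearest-center assignment and per-cluster medoid updates
    until the center set is unchanged or ``max_iter`` is reached.  The
    objective (total member-to-center distance) never increases between
    iterations.  Emptied clusters are repaired deterministically by seizing
    the member farthest from its current center.
    """
    centers = np.asarray(list(initial_centers), dtype=int)
    K = len(centers)
    if K < 1 or K > D.n:
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={D.n}")
    if len(np.unique(centers)) != K:
        raise ValueError("initial centers must be distinct")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    assignment = assign_to_nearest(D, centers)
    _repair_empty_clusters(D, assignment, centers)
    prev_obj = clustering_objective(D, assignment, centers)
    n_iter = 1
    for n_iter in range(1, max_iter + 1):
        # medoids of disjoint non-empty clusters are automatically distinct
        new_centers = np.array([medoid(D, np.flatnonzero(assignment == k))
                                for k in range(K)])
        new_assignment = assign_to_nearest(D, new_centers)
        _repair_empty_clusters(D, new_assignment, new_centers)
        obj = clustering_objective(D, new_assignment, new_centers)
        if obj > prev_obj + 1e-9:  # descent property; should never trigger
            break
        converged = np.array_equal(np.sort(new_centers), np.sort(centers))
        centers, assignment, prev_obj = new_centers, new_assignment, obj
        if converged:
            break
    logger.info("kmeans: K=%d converged in %d iterations, objective=%.4f",
                K, n_iter, prev_obj)
    return Clustering(assignment, centers, n_iter, metric=D.metric,
                      seed_method=seed_method)


def kmeans_pp_seed(D: DistanceMatrix, K: int, rng: np.random.Generator) -> List[int]:
    """K-means++ seeding over a distance matrix.

    The first center is uniform over members; each later center is drawn
    with probability proportional to its squared distance to the nearest
    already-chosen center.  Members at distance zero from a chosen center
    are never re-drawn while any positive-mass candidate remains; if all
    remaining masses are zero (fewer distinct members than K) the draw
    falls back to uniform over the unchosen members.
    """
    if not (1 <= K <= D.n):
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={D.n}")
    centers = [int(rng.integers(D.n))]
    while len(centers) < K:
        d2 = D.values[:, centers].min(axis=1) ** 2
        d2[centers] = 0.0
        total = d2.sum()
        if total <= 0.0:
            logger.warning("kmeans++ seeding: all remaining squared distances are "
                           "zero; falling back to a uniform draw")
            remaining = np.setdiff1d(np.arange(D.n), centers)
            centers.append(int(rng.choice(remaining)))
            continue
        probs = d2 / total
        centers.append(int(rng.choice(D.n, p=probs)))
    return centers


def spicker_cluster(D: DistanceMatrix, params: SpickerParams = SpickerParams()) -> Clustering:
    """SPICKER-style one-step clustering by neighbor counts.

    The pairwise cutoff self-adjusts so that the most populated
    neighborhood holds a target fraction of the ensemble; clusters are then
    extracted greedily — the member with most neighbors becomes a center
    and takes its whole neighborhood — until ``max_clusters`` clusters
    exist or no members remain.  Leftover members join the nearest center.
    Clusters are ordered by decreasing size (ties: earlier extraction).
    """
    N = D.n
    if N == 0:
        raise ValueError("cannot cluster an empty ensemble")
    V = D.values
    if N > params.representative_cap:
        keep = np.linspace(0, N - 1, params.representative_cap).astype(int)
        keep = np.unique(keep)
    else:
        keep = np.arange(N)

    # self-adjusting cutoff on the representative subset
    sub = V[np.ix_(keep, keep)]
    lo, hi = params.target_fraction_range
    c = params.initial_cutoff
    n_adjust = 1
    for n_adjust in range(1, params.max_adjust_iterations + 1):
        neigh = (sub <= c).sum(axis=1)  # includes self
        frac = neigh.max() / len(keep)
        if frac < lo:
            new_c = min(c * 1.1, params.cutoff_max)
        elif frac > hi:
            new_c = max(c * 0.9, params.cutoff_min)
        else:
            break
        if new_c == c:
            break
        c = new_c

    # greedy extraction of neighborhoods
    remaining = set(keep.tolist())
    centers: List[int] = []
    cluster_members: List[np.ndarray] = []
    while remaining and len(centers) < params.max_clusters:
        rem = np.array(sorted(remaining))
        counts = (V[np.ix_(rem, rem)] <= c).sum(axis=1)
        center = int(rem[int(np.argmax(counts))])  # ties -> lowest index
        hood = rem[V[center, rem] <= c]
        centers.append(center)
        cluster_members.append(hood)
        remaining.difference_update(hood.tolist())

    assignment = np.empty(N, dtype=int)
    assignment.fill(-1)
    for k, hood in enumerate(cluster_members):
        assignment[hood] = k
    # leftovers: subset members beyond max_clusters, plus anything thinned out
    unassigned = np.flatnonzero(assignment < 0)
    if len(unassigned):
        assignment[unassigned] = np.argmin(V[np.ix_(unassigned, centers)], axis=1)

    # order clusters by decreasing size, ties by extraction order
    sizes = np.bincount(assignment, minlength=len(centers))
    order = sorted(range(len(centers)), key=lambda k: (-sizes[k], k))
    relabel = np.empty(len(centers), dtype=int)
    relabel[np.array(order)] = np.arange(len(centers))
    assignment = relabel[assignment]
    centers_arr = np.array(centers)[np.array(order)]

    logger.info("spicker: cutoff=%.2f A after %d adjustments, K=%d, sizes=%s",
                c, n_adjust, len(centers_arr),
                np.bincount(assignment, minlength=len(centers_arr)).tolist())
    return Clustering(assignment, centers_arr, n_adjust, metric=D.metric,
                      seed_method="spicker")


def sk_means(D: DistanceMatrix, params: SpickerParams = SpickerParams(),
             max_iter: int = 100) -> Clustering:
    """SPICKER-seeded K-means: refine the SPICKER partition by Lloyd steps.

    K equals the number of clusters the SPICKER pass produced.  The final
    objective never exceeds that of the SPICKER partition evaluated with
    medoid centers on the same distance matrix.
    """
    initial = spicker_cluster(D, params)
    # re-center each SPICKER cluster on its medoid before refining
    seeds = [medoid(D, initial.members_of(k)) for k in range(initial.k)]
    refined = kmeans(D, seeds, max_iter=max_iter, seed_method="spicker")
    return refined


def kmeans_plusplus(D: DistanceMatrix, K: int = 5, max_iter: int = 100,
                    rng: Optional[np.random.Generator] = None) -> Clustering:
    """K-means with K-means++ seeding; deterministic under a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(0)
    seeds = kmeans_pp_seed(D, K, rng)
    return kmeans(D, seeds, max_iter=max_iter, seed_method="plusplus")


def select_models(clustering: Clustering, D: DistanceMatrix,
                  n_models: int = 5) -> List[int]:
    """Rank clusters and return the member index of each cluster's medoid.

    Clusters are ranked by size (largest first); ties go to the more
    compact cluster (smaller within-cluster mean distance), then to the
    lower center index.  ``model1`` — the first returned index — is the
    medoid of the top-ranked cluster, the conventional near-native pick.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    stats = []
    for k in range(clustering.k):
        members = clustering.members_of(k)
        sub = D.values[np.ix_(members, members)]
        mean_within = sub.sum() / (len(members) ** 2)
        stats.append((-len(members), mean_within, int(clustering.center_indices[k]), k))
    stats.sort()
    ranked = [k for (_, _, _, k) in stats]
    out = []
    for k in ranked[:n_models]:
        out.append(medoid(D, clustering.members_of(k)))
    return out
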