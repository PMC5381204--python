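"""Independent brute-force oracles used by the test suite.

These deliberately avoid the closed-form and heuristic paths of the
package: rigid superpositions are searched over explicit rotation grids
(hierarchically refined Euler grids), clustering optima are found by
exhaustive enumeration over center subsets, and seeding probabilities are
enumerated from their defining rule.
"""

from __future__ import annotations

from itertools import combinations
from typing import Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _euler_grid(n_alpha: int, n_beta: int, n_gamma: int) -> np.ndarray:
    """Stack of rotation matrices on a zyz Euler grid covering SO(3)."""
    a = np.linspace(0.0, 2 * np.pi, n_alpha, endpoint=False)
    b = np.linspace(0.0, np.pi, n_beta)
    g = np.linspace(0.0, 2 * np.pi, n_gamma, endpoint=False)
    angles = np.array(np.meshgrid(a, b, g, indexing="ij")).reshape(3, -1).T
    return Rotation.from_euler("zyz", angles).as_matrix()


def _local_grid(center: np.ndarray, half_width: float, n: int) -> np.ndarray:
    """Rotation matrices around ``center`` within a rotation-vector cube."""
    c = Rotation.from_matrix(center)
    offs = np.linspace(-half_width, half_width, n)
    vecs = np.array(np.meshgrid(offs, offs, offs, indexing="ij")).reshape(3, -1).T
    return (Rotation.from_rotvec(vecs) * c).as_matrix()


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                  levels: int = 4) -> Tuple[float, float]:
    """Minimum RMSD over rotations by hierarchical grid search.

    For each candidate rotation the optimal translation is closed-form
    (match centroids), so only SO(3) is searched: a coarse Euler grid
    (~15 degree spacing) followed by ``levels`` local refinements that
    shrink the step 4x each time.

    Returns ``(rmsd, resolution_bound)`` where the bound is the largest
    possible shortfall of the grid optimum from the true optimum:
    ``final_step * max_radius`` (a rotation off by angle eps moves a point
    at radius r by at most eps * r).
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def batch_rmsd(Rs: np.ndarray) -> np.ndarray:
        rot = np.einsum("rij,lj->rli", Rs, P)
        return np.sqrt(np.mean(np.sum((rot - Q) ** 2, axis=2), axis=1))

    Rs = _euler_grid(24, 13, 24)
    vals = batch_rmsd(Rs)
    # refine the best few coarse candidates independently: the coarse
    # ranking can put a secondary basin first
    starts = Rs[np.argsort(vals)[:5]]
    results = []
    final_step = None
    for start in starts:
        best = start
        step = np.deg2rad(15.0)
        for _ in range(levels):
            step /= 4.0
            Rs_loc = _local_grid(best, 2 * step, 9)
            vals_loc = batch_rmsd(Rs_loc)
            best = Rs_loc[np.argmin(vals_loc)]
        final_step = 2 * step * 2 / 8  # cube half-width over grid spacing
        results.append(float(batch_rmsd(best[None])[0]))
    radius = max(np.linalg.norm(P, axis=1).max(), np.linalg.norm(Q, axis=1).max())
    bound = final_step * radius
    return min(results), float(bound)


def _tm_value(model: np.ndarray, native: np.ndarray, d0: float) -> float:
    d = np.linalg.norm(model - native, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def grid_max_tm(model: np.ndarray, native: np.ndarray, d0: float,
                top: int = 12) -> Tuple[float, float]:
    """Maximum TM-score over rigid transforms by grid search plus local polish.

    Rotations are searched on a coarse Euler grid (~15 degree spacing).
    For every rotation, candidate translations place each model atom
    exactly onto each native atom (any near-optimal superposition brings
    some atom pair within d0, so one of these candidates lies close to the
    optimal translation).  The globally best ``top`` (rotation,
    translation) candidates are polished by a 6-parameter Nelder-Mead over
    (rotation vector, translation).  Returns ``(score, bound)`` with a
    sensitivity-based resolution bound derived from the TM integrand's
    maximum slope ``(3 sqrt(3) / 8) / d0`` and the polish displacement
    tolerance (~0.05 A).
    """
    L = len(model)
    Rs = _euler_grid(24, 13, 24)
    candidates = []  # (score, rotvec, translation)
    chunk = 400
    for s in range(0, len(Rs), chunk):
        Rc = Rs[s : s + chunk]
        moved = np.einsum("rij,lj->rli", Rc, model)          # (r, L, 3)
        # translations t[i,j] = native[j] - moved[:, i]; displaced coords for
        # candidate (i, j): moved[:, l] + t  -> distances to native[m]
        t = native[None, None, :, :] - moved[:, :, None, :]   # (r, L, L, 3)
        disp = moved[:, None, None, :, :] + t[:, :, :, None, :]  # (r, i, j, l, 3)
        d = np.linalg.norm(disp - native[None, None, None, :, :], axis=-1)
        sc = np.mean(1.0 / (1.0 + (d / d0) ** 2), axis=-1)    # (r, i, j)
        flat = sc.reshape(len(Rc), -1)
        for r_idx in range(len(Rc)):
            j = int(np.argmax(flat[r_idx]))
            candidates.append((float(flat[r_idx, j]),
                               Rotation.from_matrix(Rc[r_idx]).as_rotvec(),
                               t.reshape(len(Rc), -1, 3)[r_idx, j]))
    candidates.sort(key=lambda c: -c[0])
    best = candidates[0][0]
    for score0, rv0, t0 in candidates[:top]:
        x0 = np.concatenate([rv0, t0])

        def neg_tm(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            moved = model @ R.T + x[3:]
            return -_tm_value(moved, native, d0)

        res = minimize(neg_tm, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
        best = max(best, float(-res.fun))
    slope = (3.0 * np.sqrt(3.0) / 8.0) / d0
    bound = slope * 0.05 + 0.01
    return float(best), float(bound)


def exhaustive_kmedoids_optimum(D: np.ndarray, K: int) -> float:
    """Global optimum of the K-medoids objective by enumerating all
    K-subsets of centers with nearest-center assignment."""
    N = len(D)
    best = np.inf
    for centers in combinations(range(N), K):
        obj = D[:, centers].min(axis=1).sum()
        best = min(best, obj)
    return float(best)


def exhaustive_kmedoids_optimal_centers(D: np.ndarray, K: int) -> Tuple[float, tuple]:
    """As above, also returning one optimal center subset."""
    N = len(D)
    best, best_c = np.inf, None
    for centers in combinations(range(N), K):
        obj = D[:, centers].min(axis=1).sum()
        if obj < best:
            best, best_c = obj, centers
    return float(best), best_c


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of member pairs on which two partitions agree."""
    a = np.asarray(a)
    b = np.asarray(b)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(len(a), k=1)
    return float(np.mean(same_a[iu] == same_b[iu]))
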