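"""State and conformation clustering: k-means maps of the normalized
(SASA, Rg) plane, GROMOS trajectory clustering with automatic cutoff
search, and the cluster-dispersion stability score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from condenskit.cg_metrics.structures import BeadTrajectory

__all__ = [
    "kmeans_states",
    "pairwise_rmsd",
    "gromos_cluster",
    "GromosClustering",
    "stability_score",
    "StabilityScore",
    "CutoffSearchError",
]


class CutoffSearchError(RuntimeError):
    """Raised when no cutoff achieves the requested largest-cluster fraction."""


@dataclass(frozen=True)
class GromosClustering:
    """Iterative neighbor-count clustering result.

    ``labels[t]`` is the cluster id of frame t (0 = largest-first order of
    extraction); ``centers`` are the central frame indices.
    """

    labels: np.ndarray
    centers: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return int(self.centers.size)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def largest_fraction(self) -> float:
        return float(np.max(self.sizes()) / self.labels.size)


@dataclass(frozen=True)
class StabilityScore:
    """log10(N_max / S): large, tight clusters score high."""

    N_max: int
    S: float
    stability: float


def kmeans_states(
    points: np.ndarray, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded k-means on (SASA_norm, Rg_norm) points.

    Returns (assignments, proportions); 10 restarts, best inertia kept.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array of observations")
    if pts.shape[0] < k:
        raise ValueError(f"need at least k={k} points, got {pts.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    proportions = np.bincount(labels, minlength=k) / pts.shape[0]
    return labels, proportions


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD of two conformations after optimal rigid superposition."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    cov = a.T @ b
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    s[-1] *= sign
    # E = sum|a|^2 + sum|b|^2 - 2*sum(singular values with chirality fix)
    e0 = np.sum(a**2) + np.sum(b**2)
    msd = max(e0 - 2.0 * np.sum(s), 0.0) / a.shape[0]
    return float(np.sqrt(msd))


def pairwise_rmsd(traj: BeadTrajectory) -> np.ndarray:
    """Symmetric frame-frame RMSD matrix after Kabsch superposition."""
    n = traj.n_frames
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = _kabsch_rmsd(traj.coords[i], traj.coords[j])
    return rmsd


def _gromos_from_matrix(rmsd: np.ndarray, cutoff: float) -> GromosClustering:
    n = rmsd.shape[0]
    labels = np.full(n, -1, dtype=int)
    centers = []
    remaining = np.ones(n, dtype=bool)
    neighbor = rmsd <= cutoff
    cluster_id = 0
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))
        members = np.flatnonzero(neighbor[center] & remaining)
        labels[members] = cluster_id
        centers.append(center)
        remaining[members] = False
        cluster_id += 1
    return GromosClustering(labels=labels, centers=np.array(centers), cutoff=cutoff)


def gromos_cluster(
    traj: BeadTrajectory,
    cutoff: float | None = None,
    target_fraction: float | None = None,
    tolerance: float = 0.05,
    max_iter: int = 60,
    rmsd_matrix: np.ndarray | None = None,
) -> GromosClustering:
    """GROMOS conformational clustering of trajectory frames.

    Repeatedly takes the unassigned frame with the most RMSD neighbors
    within ``cutoff`` as a cluster center, assigns its neighbors, and
    removes them.  With ``target_fraction``, bisection on the cutoff finds
    a clustering whose largest-cluster fraction is within ``tolerance``
    (percentage points) of the target, emulating the "largest cluster
    ~= 50%" protocol.
    """
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames to cluster")
    if (cutoff is None) == (target_fraction is None):
        raise ValueError("provide exactly one of cutoff or target_fraction")
    rmsd = pairwise_rmsd(traj) if rmsd_matrix is None else np.asarray(rmsd_matrix)

    if cutoff is not None:
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        return _gromos_from_matrix(rmsd, cutoff)

    off_diag = rmsd[np.triu_indices_from(rmsd, k=1)]
    lo, hi = 0.0, float(np.max(off_diag)) + 1e-12
    # fraction is monotone non-decreasing in cutoff: bisect
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        result = _gromos_from_matrix(rmsd, mid)
        frac = result.largest_fraction
        if abs(frac - target_fraction) <= tolerance:
            best = result
            break
        if frac < target_fraction:
            lo = mid
        else:
            hi = mid
    if best is None:
        lo_frac = _gromos_from_matrix(rmsd, lo).largest_fraction
        hi_frac = _gromos_from_matrix(rmsd, hi).largest_fraction
        raise CutoffSearchError(
            f"no cutoff reaches largest-cluster fraction {target_fraction} "
            f"+/- {tolerance}; achievable bracket is "
            f"[{lo_frac:.3f} @ {lo:.4g} nm, {hi_frac:.3f} @ {hi:.4g} nm]"
        )
    return best


def stability_score(
    points: np.ndarray,
    clusters: np.ndarray,
    grid: int = 50,
    method: str = "grid",
) -> StabilityScore:
    """Dispersion-based stability of the most populated cluster.

    ``points`` are normalized (SASA, Rg) pairs in the unit square;
    ``clusters`` their cluster assignments.  N_max is the largest
    cluster's size and S its occupied area: the fraction of cells of a
    ``grid`` x ``grid`` partition of the unit square containing at least
    one of its points (floored at one cell), or the convex-hull area with
    ``method="hull"``.  Score = log10(N_max / S).
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(clusters)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) normalized pairs")
    if labels.shape != (pts.shape[0],) or pts.shape[0] == 0:
        raise ValueError("one cluster label per point required; input non-empty")

    unique, counts = np.unique(labels, return_counts=True)
    winner = unique[np.argmax(counts)]
    members = pts[labels == winner]
    n_max = int(members.shape[0])

    if method == "grid":
        cells = np.clip((members * grid).astype(int), 0, grid - 1)
        occupied = len({(int(i), int(j)) for i, j in cells})
        S = max(occupied, 1) / (grid * grid)
    elif method == "hull":
        from scipy.spatial import ConvexHull, QhullError

        try:
            S = max(float(ConvexHull(members).volume), 1.0 / (grid * grid))
        except QhullError:
            S = 1.0 / (grid * grid)
    else:
        raise ValueError(f"unknown dispersion method {method!r}")
    return StabilityScore(N_max=n_max, S=float(S), stability=float(np.log10(n_max / S)))
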