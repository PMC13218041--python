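"""Geometric per-frame metrics: radius of gyration, Shrake-Rupley SASA,
metric normalization, and intramolecular contact maps.
"""

from __future__ import annotations

import numpy as np

from condenskit.cg_metrics.structures import (
    BeadTopology,
    BeadTrajectory,
    MetricSeries,
    displacement,
)

__all__ = [
    "radius_of_gyration",
    "sasa",
    "sphere_points",
    "normalize_series",
    "contact_map",
]

DEFAULT_PROBE_NM = 0.14
DEFAULT_SPHERE_POINTS = 960


def radius_of_gyration(
    frame: np.ndarray, selection: np.ndarray | None = None
) -> float:
    """Uniform-mass radius of gyration (nm) about the selection centroid."""
    coords = np.asarray(frame, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("frame must have shape (n_beads, 3)")
    if selection is not None:
        selection = np.asarray(selection)
        if selection.size == 0:
            raise ValueError("empty selection")
        coords = coords[selection]
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere quadrature points (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one quadrature point")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    frame: np.ndarray,
    topology: BeadTopology | np.ndarray,
    probe: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Each bead is expanded to radius ``r_i + probe``; quadrature points on
    that sphere count as accessible when they fall outside every other
    expanded sphere.  ``topology`` may also be a plain per-bead radius
    array.
    """
    coords = np.asarray(frame, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("frame must have shape (n_beads, 3)")
    radii = (
        topology.radius if isinstance(topology, BeadTopology) else np.asarray(topology, dtype=float)
    )
    if radii.shape != (coords.shape[0],):
        raise ValueError("one radius per bead required")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")

    n_beads = coords.shape[0]
    expanded = radii + probe
    unit = sphere_points(n_points)

    # neighbor prefilter: bead pairs whose expanded spheres can intersect
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    can_occlude = dist < (expanded[:, None] + expanded[None, :])
    np.fill_diagonal(can_occlude, False)

    total = 0.0
    for i in range(n_beads):
        pts = coords[i] + expanded[i] * unit
        neighbors = np.flatnonzero(can_occlude[i])
        if neighbors.size:
            d2 = np.sum(
                (pts[:, None, :] - coords[neighbors][None, :, :]) ** 2, axis=-1
            )
            buried = np.any(d2 < expanded[neighbors][None, :] ** 2, axis=1)
            accessible = float(np.count_nonzero(~buried)) / n_points
        else:
            accessible = 1.0
        total += accessible * 4.0 * np.pi * expanded[i] ** 2
    return float(total)


def normalize_series(X_t: np.ndarray) -> MetricSeries:
    """Min-max normalize a per-frame metric series to [0, 1]."""
    X = np.asarray(X_t, dtype=float)
    if X.ndim != 1 or X.size < 2:
        raise ValueError("series must be 1-D with >= 2 values")
    lo, hi = float(np.min(X)), float(np.max(X))
    if hi <= lo:
        raise ValueError("constant series cannot be min-max normalized")
    return MetricSeries(X_t=X, X_norm=(X - lo) / (hi - lo), X_min=lo, X_max=hi)


def contact_map(
    traj: BeadTrajectory,
    residues: np.ndarray,
    cutoff: float,
    min_separation: int = 2,
) -> np.ndarray:
    """Residue-residue contact probabilities over a trajectory.

    ``residues`` assigns a residue index to every bead.  ``P[i, j]`` is
    the fraction of frames in which any bead of residue i lies within
    ``cutoff`` (nm) of any bead of residue j; pairs closer in sequence
    than ``min_separation`` are masked to 0.  Symmetric by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = np.asarray(residues)
    if residues.shape != (traj.n_beads,):
        raise ValueError("one residue index per bead required")
    unique = np.unique(residues)
    n_res = unique.size
    res_beads = [np.flatnonzero(residues == r) for r in unique]

    counts = np.zeros((n_res, n_res))
    for frame in traj.coords:
        d = np.linalg.norm(
            displacement(frame[:, None, :], frame[None, :, :], traj.box_edge), axis=-1
        )
        for a in range(n_res):
            for b in range(a + 1, n_res):
                if np.min(d[np.ix_(res_beads[a], res_beads[b])]) <= cutoff:
                    counts[a, b] += 1
                    counts[b, a] += 1
    P = counts / traj.n_frames
    sep = np.abs(unique[:, None] - unique[None, :])
    P[sep < min_separation] = 0.0
    return P
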