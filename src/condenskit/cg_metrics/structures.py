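"""Bead-model trajectory and topology containers.

Coordinates are stored in nm throughout.  A cubic box edge (nm) enables
minimum-image distances; without one, boundaries are open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeadTopology",
    "BeadTrajectory",
    "MetricSeries",
    "subsample_frames",
    "displacement",
]

DEFAULT_BEAD_RADIUS_NM = 0.264


@dataclass(frozen=True)
class BeadTopology:
    """Per-bead parameters: radius/charge/LJ plus molecule and residue labels.

    Units: radius and sigma in nm, charge in e, epsilon in kJ/mol.
    Residue indices must be contiguous within each molecule.
    """

    radius: np.ndarray
    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    molecule: np.ndarray
    residue: np.ndarray
    name: np.ndarray

    def __post_init__(self) -> None:
        radius = np.asarray(self.radius, dtype=float)
        n = radius.size
        object.__setattr__(self, "radius", radius)
        for attr, dtype in (
            ("charge", float), ("sigma", float), ("epsilon", float),
            ("molecule", None), ("residue", int), ("name", None),
        ):
            arr = np.asarray(getattr(self, attr))
            if dtype is not None:
                arr = arr.astype(dtype)
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have one entry per bead ({n})")
            object.__setattr__(self, attr, arr)
        if np.any(self.radius <= 0) or np.any(self.sigma <= 0):
            raise ValueError("bead radii and LJ sigma must be positive")
        for mol in np.unique(self.molecule):
            res = np.sort(np.unique(self.residue[self.molecule == mol]))
            if res.size > 1 and np.any(np.diff(res) != 1):
                raise ValueError(
                    f"residue indices of molecule {mol!r} are not contiguous"
                )

    @property
    def n_beads(self) -> int:
        return int(self.radius.size)

    def select(self, molecule: str | None = None, residues=None) -> np.ndarray:
        """Bead indices matching a molecule label and/or residue list."""
        mask = np.ones(self.n_beads, dtype=bool)
        if molecule is not None:
            mask &= self.molecule == molecule
        if residues is not None:
            mask &= np.isin(self.residue, np.asarray(residues))
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class BeadTrajectory:
    """Ordered frames of bead coordinates (nm).

    ``coords`` has shape (n_frames, n_beads, 3).  ``frame_spacing_ns``
    records the sampling interval; ``box_edge`` a cubic box edge in nm
    (None = open boundaries).
    """

    coords: np.ndarray
    frame_spacing_ns: float = 1.0
    box_edge: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.box_edge is not None and self.box_edge <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_beads(self) -> int:
        return int(self.coords.shape[1])

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing_ns


@dataclass(frozen=True)
class MetricSeries:
    """A raw per-frame metric together with its min-max normalization."""

    X_t: np.ndarray
    X_norm: np.ndarray = field(repr=False)
    X_min: float
    X_max: float

    @property
    def T(self) -> int:
        return int(self.X_t.size)

    def denormalize(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) * (self.X_max - self.X_min) + self.X_min


def subsample_frames(
    traj: BeadTrajectory,
    start_ns: float,
    stop_ns: float,
    every_ns: float,
) -> BeadTrajectory:
    """Extract frames in the half-open window [start_ns, stop_ns) every ``every_ns``.

    Frame times are ``index * frame_spacing_ns``.  Sampling one frame per
    ns over a 1000-ns window yields 1000 frames.
    """
    if every_ns <= 0:
        raise ValueError("every_ns must be positive")
    if stop_ns <= start_ns:
        raise ValueError("stop_ns must exceed start_ns")
    times = traj.times_ns
    offsets = times - start_ns
    remainder = np.mod(offsets, every_ns)
    on_grid = np.isclose(remainder, 0.0, atol=1e-9) | np.isclose(
        remainder, every_ns, atol=1e-9
    )
    keep = (times >= start_ns) & (times < stop_ns) & on_grid
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    return BeadTrajectory(
        coords=traj.coords[idx],
        frame_spacing_ns=every_ns,
        box_edge=traj.box_edge,
    )


def displacement(
    a: np.ndarray, b: np.ndarray, box_edge: float | None = None
) -> np.ndarray:
    """Displacement vectors b - a, minimum-image wrapped for cubic boxes."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box_edge is not None:
        d -= box_edge * np.round(d / box_edge)
    return d
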