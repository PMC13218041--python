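"""DNA-component interaction statistics and the empirical FRET score.

The empirical FRET score rewards terminal-bead pairs that stay both close
and steady: ``E = (alpha / n) * sum_i 1 / (dbar_ii * v_ii)`` over terminal
pairs i, with dbar the mean inter-terminal distance (nm) over frames and
v its standard deviation (floored to avoid blow-up on rigid ensembles).

The tight-binding cutoff averages, over frames and DNA residues, the
per-residue mean of each bead's shortest distance to the partner
component; it is reported in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from condenskit.cg_metrics.structures import BeadTrajectory, displacement

__all__ = [
    "EmpiricalFretResult",
    "InteractionCutoff",
    "empirical_fret",
    "interaction_cutoff",
    "interaction_profile",
]

V_FLOOR_NM = 1e-3
NM_TO_ANGSTROM = 10.0


@dataclass(frozen=True)
class EmpiricalFretResult:
    """Terminal-distance FRET score and its per-pair statistics."""

    E_FRET: float
    alpha: float
    n: int
    d_bar_ii: np.ndarray
    v_ii: np.ndarray
    v_floored: bool = False


@dataclass(frozen=True)
class InteractionCutoff:
    """Tight-binding distance cutoff with its per-frame per-residue inputs."""

    d_cutoff: float  # Angstrom
    d_im: np.ndarray = field(repr=False)  # (T, n_residues), Angstrom
    T: int
    n_i: np.ndarray = field(repr=False)  # beads per residue


def empirical_fret(
    traj: BeadTrajectory,
    terminal_pairs: list[tuple[int, int]],
    alpha: float = 1.0,
    v_floor: float = V_FLOOR_NM,
) -> EmpiricalFretResult:
    """Empirical FRET efficiency from terminal-bead distance statistics.

    For each (i5', i3') bead pair, the mean and sample SD (ddof=1) of the
    inter-bead distance over frames feed
    ``E = (alpha / n) * sum 1 / (dbar * v)``.  SDs below ``v_floor`` nm
    (rigid ensembles) are floored with a warning flag.
    """
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames for a distance standard deviation")
    if not terminal_pairs:
        raise ValueError("at least one terminal bead pair required")
    d_bar, v = [], []
    for i, j in terminal_pairs:
        if not (0 <= i < traj.n_beads and 0 <= j < traj.n_beads):
            raise IndexError(f"terminal pair ({i}, {j}) out of range")
        vec = displacement(traj.coords[:, i, :], traj.coords[:, j, :], traj.box_edge)
        dist = np.linalg.norm(vec, axis=1)
        d_bar.append(float(np.mean(dist)))
        v.append(float(np.std(dist, ddof=1)))
    d_bar = np.array(d_bar)
    v_raw = np.array(v)
    floored = bool(np.any(v_raw < v_floor))
    if floored:
        warnings.warn(
            "rigid terminal-distance distribution: SD floored at "
            f"{v_floor:g} nm for the FRET score",
            stacklevel=2,
        )
    v_eff = np.maximum(v_raw, v_floor)
    n = len(terminal_pairs)
    E = float(alpha / n * np.sum(1.0 / (d_bar * v_eff)))
    return EmpiricalFretResult(
        E_FRET=E, alpha=alpha, n=n, d_bar_ii=d_bar, v_ii=v_raw, v_floored=floored
    )


def _residue_groups(residues: np.ndarray, beads: np.ndarray) -> list[np.ndarray]:
    residues = np.asarray(residues)
    order = np.unique(residues[beads])
    return [beads[residues[beads] == r] for r in order]


def interaction_cutoff(
    traj: BeadTrajectory,
    residues: np.ndarray,
    group_A: np.ndarray,
    group_B: np.ndarray,
) -> InteractionCutoff:
    """Tight-binding cutoff (Angstrom) between DNA residues and a component.

    Per frame t and DNA residue i: each bead j of the residue contributes
    its shortest distance to any bead of the component; the residue value
    is the mean over its beads; the cutoff is the average of those values
    over residues and frames.
    """
    group_A = np.asarray(group_A)
    group_B = np.asarray(group_B)
    if group_A.size == 0 or group_B.size == 0:
        raise ValueError("both bead groups must be non-empty")
    residue_beads = _residue_groups(residues, group_A)
    n_i = np.array([g.size for g in residue_beads])

    d_im = np.empty((traj.n_frames, len(residue_beads)))
    for t, frame in enumerate(traj.coords):
        b_coords = frame[group_B]
        for r, beads in enumerate(residue_beads):
            diff = displacement(
                frame[beads][:, None, :], b_coords[None, :, :], traj.box_edge
            )
            d_jm = np.min(np.linalg.norm(diff, axis=-1), axis=1)
            d_im[t, r] = np.mean(d_jm)
    d_im_ang = d_im * NM_TO_ANGSTROM
    return InteractionCutoff(
        d_cutoff=float(np.mean(d_im_ang)),
        d_im=d_im_ang,
        T=traj.n_frames,
        n_i=n_i,
    )


def interaction_profile(
    traj: BeadTrajectory,
    residues: np.ndarray,
    group_A: np.ndarray,
    group_B: np.ndarray,
    cutoff_angstrom: float,
) -> np.ndarray:
    """Mean number of component beads bound to each DNA residue.

    A component bead counts toward residue i in a frame when it lies
    within ``cutoff_angstrom`` of any bead of that residue; the profile is
    the per-residue mean count over frames.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    group_A = np.asarray(group_A)
    group_B = np.asarray(group_B)
    if group_A.size == 0 or group_B.size == 0:
        raise ValueError("both bead groups must be non-empty")
    cutoff_nm = cutoff_angstrom / NM_TO_ANGSTROM
    residue_beads = _residue_groups(residues, group_A)

    profile = np.zeros(len(residue_beads))
    for frame in traj.coords:
        b_coords = frame[group_B]
        for r, beads in enumerate(residue_beads):
            diff = displacement(
                frame[beads][:, None, :], b_coords[None, :, :], traj.box_edge
            )
            d = np.linalg.norm(diff, axis=-1)  # (n_beads_res, n_B)
            profile[r] += np.count_nonzero(np.any(d <= cutoff_nm, axis=0))
    return profile / traj.n_frames
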