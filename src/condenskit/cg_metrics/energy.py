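"""Pairwise nonbonded energies: Lennard-Jones 12-6 plus reaction-field
Coulomb, truncated at a cutoff (default 1.1 nm), with the intermolecular
decomposition ``E_inter(AB) = E(AB) - E(A) - E(B)``.

Reaction-field Coulomb (GROMACS convention)::

    V(r) = f * q_i q_j / eps_r * (1/r + k_rf r^2 - c_rf),  r <= r_c
    k_rf = (eps_rf - eps_r) / (2 eps_rf + eps_r) / r_c^3
    c_rf = 1/r_c + k_rf r_c^2

with ``f = 138.935458 kJ mol^-1 nm e^-2``.  Defaults follow Martini
practice: eps_r = 15, eps_rf -> infinity (k_rf = 1 / (2 r_c^3)).
Lorentz-Berthelot combination rules (arithmetic sigma, geometric epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from condenskit.cg_metrics.structures import BeadTopology, displacement

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyDecomposition",
    "pair_energy",
    "nonbonded_energy",
]

COULOMB_CONSTANT = 138.935458  # kJ mol^-1 nm e^-2
DEFAULT_CUTOFF_NM = 1.1
DEFAULT_EPS_R = 15.0
MIN_SEPARATION_NM = 1e-4


@dataclass(frozen=True)
class EnergyDecomposition:
    """Nonbonded energies (kJ/mol) of two groups and their cross term."""

    E_AB: float
    E_A: float
    E_B: float

    @property
    def E_inter(self) -> float:
        return self.E_AB - self.E_A - self.E_B


def _rf_constants(cutoff: float, eps_r: float, eps_rf: float | None):
    if eps_rf is None or np.isinf(eps_rf):
        k_rf = 1.0 / (2.0 * cutoff**3)
    else:
        k_rf = (eps_rf - eps_r) / (2.0 * eps_rf + eps_r) / cutoff**3
    c_rf = 1.0 / cutoff + k_rf * cutoff**2
    return k_rf, c_rf


def pair_energy(
    r: float,
    qi: float,
    qj: float,
    sigma: float,
    epsilon: float,
    cutoff: float = DEFAULT_CUTOFF_NM,
    eps_r: float = DEFAULT_EPS_R,
    eps_rf: float | None = None,
) -> float:
    """LJ + reaction-field Coulomb energy (kJ/mol) of one bead pair at distance r (nm)."""
    if r < MIN_SEPARATION_NM:
        raise FloatingPointError(f"beads overlap (r = {r:g} nm); energy singular")
    if r > cutoff:
        return 0.0
    sr6 = (sigma / r) ** 6
    lj = 4.0 * epsilon * (sr6**2 - sr6)
    k_rf, c_rf = _rf_constants(cutoff, eps_r, eps_rf)
    coul = COULOMB_CONSTANT * qi * qj / eps_r * (1.0 / r + k_rf * r**2 - c_rf)
    return float(lj + coul)


def _group_energy(
    coords: np.ndarray,
    top: BeadTopology,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    within: bool,
    cutoff: float,
    eps_r: float,
    eps_rf: float | None,
    box_edge: float | None,
) -> float:
    """Sum of pair energies, either within one group or across two groups."""
    if within:
        ii, jj = np.triu_indices(idx_a.size, k=1)
        pairs_i, pairs_j = idx_a[ii], idx_a[jj]
    else:
        pairs_i = np.repeat(idx_a, idx_b.size)
        pairs_j = np.tile(idx_b, idx_a.size)
    if pairs_i.size == 0:
        return 0.0
    d = np.linalg.norm(
        displacement(coords[pairs_i], coords[pairs_j], box_edge), axis=1
    )
    if np.any(d < MIN_SEPARATION_NM):
        raise FloatingPointError("overlapping beads (r < 1e-4 nm); energy singular")
    mask = d <= cutoff
    if not mask.any():
        return 0.0
    d = d[mask]
    i, j = pairs_i[mask], pairs_j[mask]
    sigma = 0.5 * (top.sigma[i] + top.sigma[j])
    epsilon = np.sqrt(top.epsilon[i] * top.epsilon[j])
    sr6 = (sigma / d) ** 6
    lj = 4.0 * epsilon * (sr6**2 - sr6)
    k_rf, c_rf = _rf_constants(cutoff, eps_r, eps_rf)
    coul = (
        COULOMB_CONSTANT
        * top.charge[i]
        * top.charge[j]
        / eps_r
        * (1.0 / d + k_rf * d**2 - c_rf)
    )
    return float(np.sum(lj + coul))


def nonbonded_energy(
    frames: np.ndarray,
    topology: BeadTopology,
    group_A: np.ndarray,
    group_B: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_NM,
    eps_r: float = DEFAULT_EPS_R,
    eps_rf: float | None = None,
    box_edge: float | None = None,
) -> EnergyDecomposition:
    """Frame-averaged nonbonded energy decomposition of two bead groups.

    ``frames`` is a single (n_beads, 3) frame or a stack of frames;
    energies are averaged over frames.  ``E_inter = E_AB - E_A - E_B``
    equals the cross-group pair sum and is exactly 0 when no A-B pair
    lies within the cutoff.
    """
    coords = np.asarray(frames, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("frames must have shape (n_beads, 3) or (n_frames, n_beads, 3)")
    idx_a = np.asarray(group_A)
    idx_b = np.asarray(group_B)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups must be disjoint")
    if topology.n_beads < coords.shape[1]:
        raise ValueError("topology has fewer beads than the frame")

    kw = dict(cutoff=cutoff, eps_r=eps_r, eps_rf=eps_rf, box_edge=box_edge)
    E_A = E_B = E_cross = 0.0
    for frame in coords:
        E_A += _group_energy(frame, topology, idx_a, idx_a, True, **kw)
        E_B += _group_energy(frame, topology, idx_b, idx_b, True, **kw)
        E_cross += _group_energy(frame, topology, idx_a, idx_b, False, **kw)
    n = coords.shape[0]
    E_A /= n
    E_B /= n
    E_cross /= n
    return EnergyDecomposition(E_AB=E_A + E_B + E_cross, E_A=E_A, E_B=E_B)
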