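"""Seeded generators for every input class the analysis modules consume.

Each generator returns its artifact together with a ground-truth dict so
downstream fits can be validated by parameter recovery.  All randomness
flows through ``numpy.random.default_rng(seed)``; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from condenskit.cg_metrics.structures import BeadTopology, BeadTrajectory
from condenskit.frap_kinetics import FrapTrace
from condenskit.fusion_dynamics import FusionEvent
from condenskit.saxs_analysis import ScatteringCurve
from condenskit.sequence_design import NucleotideSequence
from condenskit.spectro_fret import EmissionSpectrum

__all__ = [
    "GeneratorSpec",
    "generate",
    "gen_polymer_ensemble",
    "gen_frap_trace",
    "gen_fusion_event",
    "gen_melt_curve",
    "gen_scattering",
    "gen_spectra_pair",
    "gen_sequence_set",
    "debye_intensity",
    "sphere_intensity",
]

_KINDS = (
    "polymer_ensemble",
    "frap_trace",
    "fusion_event",
    "melt_curve",
    "scattering_curve",
    "sequence_set",
    "spectra_pair",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative recipe: kind + parameters + seed (+ replicate count)."""

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    n: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; one of {_KINDS}")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


def generate(spec: GeneratorSpec) -> list[tuple[Any, dict[str, Any]]]:
    """Run a GeneratorSpec, returning ``n`` (artifact, ground_truth) pairs."""
    dispatch = {
        "polymer_ensemble": gen_polymer_ensemble,
        "frap_trace": gen_frap_trace,
        "fusion_event": gen_fusion_event,
        "melt_curve": gen_melt_curve,
        "scattering_curve": gen_scattering,
        "sequence_set": gen_sequence_set,
        "spectra_pair": gen_spectra_pair,
    }
    fn = dispatch[spec.kind]
    return [fn(seed=spec.seed + i, **spec.parameters) for i in range(spec.n)]


# ---------------------------------------------------------------------------
# polymer ensembles


def gen_polymer_ensemble(
    n_beads: int = 76,
    compactness: float = 0.0,
    n_frames: int = 100,
    bond_length: float = 0.5,
    binder_count: int = 0,
    binder_affinity_sites: tuple[int, ...] = (),
    binder_residence: float = 1.0,
    binder_contact_distance: float = 0.3,
    bead_radius: float = 0.264,
    seed: int = 0,
) -> tuple[tuple[BeadTrajectory, BeadTopology], dict[str, Any]]:
    """Freely jointed chain ensemble with tunable compaction and binders.

    Each frame is an independent random walk of ``n_beads`` beads with
    step ``bond_length`` (nm), then contracted toward its centroid by
    ``1 / (1 + compactness)`` — compactness 0 reproduces ideal-chain
    statistics (mean Rg ~ b * sqrt(N/6)); larger values shrink Rg, SASA,
    and terminal-distance spread together, emulating folded states.

    ``binder_count`` extra beads model a peptide component: with
    probability ``binder_residence`` a binder sits within
    ``binder_contact_distance`` of one of the ``binder_affinity_sites``
    residues; otherwise it is placed far from the chain.  Default sizes
    (76-bead chain, 15 binders) mirror a tRNA-length construct with a
    15:1 peptide excess.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads")
    if compactness < 0:
        raise ValueError("compactness must be >= 0")
    if not 0.0 <= binder_residence <= 1.0:
        raise ValueError("binder_residence must lie in [0, 1]")
    if binder_count and not binder_affinity_sites:
        raise ValueError("binders require at least one affinity site")
    rng = np.random.default_rng(seed)
    shrink = 1.0 / (1.0 + compactness)

    frames = np.empty((n_frames, n_beads + binder_count, 3))
    for f in range(n_frames):
        steps = rng.normal(size=(n_beads - 1, 3))
        steps *= bond_length / np.linalg.norm(steps, axis=1, keepdims=True)
        chain = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        centroid = chain.mean(axis=0)
        chain = centroid + (chain - centroid) * shrink
        frames[f, :n_beads] = chain
        for b in range(binder_count):
            if rng.random() < binder_residence:
                site = binder_affinity_sites[b % len(binder_affinity_sites)]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                offset = binder_contact_distance * (0.5 + 0.5 * rng.random())
                frames[f, n_beads + b] = chain[site] + direction * offset
            else:
                far = rng.normal(size=3)
                far /= np.linalg.norm(far)
                span = bond_length * n_beads
                frames[f, n_beads + b] = centroid + far * span * (2.0 + rng.random())

    n_total = n_beads + binder_count
    molecule = np.array(["DNA"] * n_beads + ["PEP"] * binder_count)
    residue = np.concatenate(
        [np.arange(n_beads), np.arange(binder_count)]
    ).astype(int)
    topology = BeadTopology(
        radius=np.full(n_total, bead_radius),
        charge=np.concatenate(
            [np.full(n_beads, -1.0), np.full(binder_count, +1.0)]
        ),
        sigma=np.full(n_total, 0.47),
        epsilon=np.full(n_total, 2.0),
        molecule=molecule,
        residue=residue,
        name=np.array(
            [f"D{i}" for i in range(n_beads)] + [f"P{i}" for i in range(binder_count)]
        ),
    )
    traj = BeadTrajectory(coords=frames, frame_spacing_ns=1.0)
    truth = {
        "n_beads": n_beads,
        "compactness": compactness,
        "bond_length": bond_length,
        "ideal_rg": bond_length * np.sqrt(n_beads / 6.0),
        "expected_rg_scale": shrink,
        "binder_count": binder_count,
        "binder_affinity_sites": tuple(binder_affinity_sites),
        "binder_residence": binder_residence,
        "binder_contact_distance": binder_contact_distance,
        "seed": seed,
    }
    return (traj, topology), truth


# ---------------------------------------------------------------------------
# FRAP


def gen_frap_trace(
    a: float = 70.0,
    b: float = 70.0,
    c: float = 0.9,
    noise_sd: float = 0.0,
    reference_bleach_rate: float = 0.0,
    background_level: float = 50.0,
    n_points: int = 60,
    dt: float = 1.0,
    i_pre: float = 1000.0,
    i_min: float = 100.0,
    seed: int = 0,
) -> tuple[FrapTrace, dict[str, Any]]:
    """Three-channel FRAP trace whose pipeline ground truth is ``a - b c^t``.

    The clean normalized recovery ``y(t) = a - b * c**t`` (percent of
    prebleach) is mapped to processed intensities between ``i_min`` (the
    experiment minimum, stored in the ground truth) and ``i_pre``; the
    reference channel bleaches linearly by ``reference_bleach_rate``
    (fraction lost by the final time point) and the background sits at
    ``background_level`` — the distortions invert exactly under double
    normalization at zero noise.
    """
    if not 0.0 < c < 1.0:
        raise ValueError("exponential base c must lie in (0, 1)")
    if not 0.0 <= reference_bleach_rate < 1.0:
        raise ValueError("reference_bleach_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float) * dt
    y_clean = a - b * np.power(c, t)
    processed = i_min + (i_pre - i_min) * y_clean / 100.0

    g = 1.0 - reference_bleach_rate * (t / t[-1] if t[-1] > 0 else 0.0)
    R3 = np.full_like(t, background_level)
    ref_gap_pre = 500.0
    R2 = R3 + ref_gap_pre * g
    R1 = processed * g + R3
    if noise_sd > 0:
        R1 = R1 + rng.normal(scale=noise_sd * (i_pre - i_min) / 100.0, size=t.size)
    trace = FrapTrace(
        t=t,
        I_R1=R1,
        I_R2=R2,
        I_R3=R3,
        I_R1_pre=i_pre + background_level,
        I_R2_pre=R3[0] + ref_gap_pre,
        I_R3_pre=background_level,
    )
    t_half = (
        float(np.log(a / (2.0 * b)) / np.log(c)) if b > a / 2.0 else 0.0
    )
    truth = {
        "a": a,
        "b": b,
        "c": c,
        "t_half": t_half,
        "i_min": i_min,
        "i_pre": i_pre,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# fusion


def gen_fusion_event(
    AR0: float = 1.8,
    tau: float = 5.0,
    duration: float = 30.0,
    frame_rate: float = 7.6,
    noise_sd: float = 0.0,
    short_axis: float = 2.0,
    seed: int = 0,
) -> tuple[FusionEvent, dict[str, Any]]:
    """Single-exponential aspect-ratio relaxation sampled at ``frame_rate`` Hz."""
    if AR0 < 1.0 or tau <= 0:
        raise ValueError("need AR0 >= 1 and tau > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / frame_rate)
    AR = 1.0 + (AR0 - 1.0) * np.exp(-t / tau)
    if noise_sd > 0:
        AR = AR + rng.normal(scale=noise_sd, size=t.size)
    AR = np.maximum(AR, 1.0)
    event = FusionEvent(t=t, l_long=AR * short_axis, l_short=np.full_like(t, short_axis))
    truth = {"AR0": AR0, "tau": tau, "noise_sd": noise_sd, "seed": seed}
    return event, truth


# ---------------------------------------------------------------------------
# melt curves


def gen_melt_curve(
    Tm: float = 32.2,
    dT: float = 3.0,
    plateaus: tuple[float, float] = (100.0, 0.0),
    noise_sd: float = 0.0,
    temps: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], dict[str, Any]]:
    """Boltzmann-sigmoid renaturation curve plus optional Gaussian noise.

    ``plateaus = (A1, A2)`` are the low- and high-temperature asymptotes
    of ``y = A2 + (A1 - A2) / (1 + exp((T - Tm)/dT))``.
    """
    if temps is None:
        temps = np.arange(5.0, 90.5, 1.0)
    T = np.asarray(temps, dtype=float)
    if not T.min() < Tm < T.max():
        raise ValueError("temperature grid must span Tm")
    A1, A2 = plateaus
    rng = np.random.default_rng(seed)
    y = A2 + (A1 - A2) / (1.0 + np.exp((T - Tm) / dT))
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd * abs(A1 - A2), size=T.size)
    truth = {"Tm": Tm, "dT": dT, "A1": A1, "A2": A2, "noise_sd": noise_sd, "seed": seed}
    return (T, y), truth


# ---------------------------------------------------------------------------
# scattering


def debye_intensity(q: np.ndarray, Rg: float, I0: float = 1.0) -> np.ndarray:
    """Debye form factor of a Gaussian chain; q and Rg in matching units."""
    x = (np.asarray(q, dtype=float) * Rg) ** 2
    out = np.full_like(x, I0, dtype=float)
    nz = x > 1e-12
    out[nz] = I0 * 2.0 * (np.exp(-x[nz]) + x[nz] - 1.0) / x[nz] ** 2
    return out


def sphere_intensity(q: np.ndarray, R: float, I0: float = 1.0) -> np.ndarray:
    """Form factor of a homogeneous sphere of radius R (same units as 1/q)."""
    qR = np.asarray(q, dtype=float) * R
    amp = np.ones_like(qR)
    nz = qR > 1e-12
    amp[nz] = 3.0 * (np.sin(qR[nz]) - qR[nz] * np.cos(qR[nz])) / qR[nz] ** 3
    return I0 * amp**2


def gen_scattering(
    model: str = "debye_chain",
    size_nm: float = 2.0,
    I0: float = 1000.0,
    q_grid: np.ndarray | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[ScatteringCurve, dict[str, Any]]:
    """Analytic Debye-chain or sphere curve on the instrument q-range.

    ``size_nm`` is the chain Rg (debye_chain) or sphere radius (sphere);
    the default grid covers 0.002-0.3 inverse Angstrom.  Multiplicative
    lognormal-free Gaussian noise of relative width ``noise_frac``.
    """
    if size_nm <= 0:
        raise ValueError("size must be positive")
    if q_grid is None:
        q_grid = np.linspace(0.002, 0.3, 400)
    q = np.asarray(q_grid, dtype=float)
    size_ang = size_nm * 10.0
    if model == "debye_chain":
        I = debye_intensity(q, size_ang, I0)
        rg_nm = size_nm
    elif model == "sphere":
        I = sphere_intensity(q, size_ang, I0)
        rg_nm = size_nm * np.sqrt(3.0 / 5.0)
    else:
        raise ValueError(f"unknown scattering model {model!r}")
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        I = I * (1.0 + rng.normal(scale=noise_frac, size=q.size))
    truth = {
        "model": model,
        "size_nm": size_nm,
        "Rg_nm": rg_nm,
        "I0": I0,
        "noise_frac": noise_frac,
        "seed": seed,
    }
    return ScatteringCurve(q=q, I=I), truth


# ---------------------------------------------------------------------------
# spectra


def gen_spectra_pair(
    E_true: float = 0.3,
    donor_peak: float = 568.0,
    acceptor_peak: float = 667.0,
    donor_amplitude: float = 1000.0,
    bandwidth: float = 20.0,
    noise_sd: float = 0.0,
    wavelengths: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[tuple[EmissionSpectrum, EmissionSpectrum], dict[str, Any]]:
    """Donor-only and donor-acceptor emission spectra with known efficiency.

    The donor Gaussian band is scaled by ``1 - E_true`` in the pair
    spectrum and the transferred intensity reappears in an acceptor band,
    so ``fret_efficiency`` at the donor peak recovers ``E_true`` exactly
    at zero noise.
    """
    if not 0.0 <= E_true < 1.0:
        raise ValueError("E_true must lie in [0, 1)")
    if wavelengths is None:
        wavelengths = np.arange(566.0, 700.5, 1.0)
    wl = np.asarray(wavelengths, dtype=float)
    rng = np.random.default_rng(seed)

    donor_band = donor_amplitude * np.exp(-0.5 * ((wl - donor_peak) / bandwidth) ** 2)
    acceptor_shape = np.exp(-0.5 * ((wl - acceptor_peak) / bandwidth) ** 2)
    # pin the acceptor band to exactly zero at the donor readout peak so
    # the donor-channel round trip recovers E_true exactly at zero noise
    leak = np.exp(-0.5 * ((donor_peak - acceptor_peak) / bandwidth) ** 2)
    acceptor_band = E_true * donor_amplitude * np.clip(acceptor_shape - leak, 0.0, None)
    donor_only = donor_band.copy()
    pair = (1.0 - E_true) * donor_band + acceptor_band
    if noise_sd > 0:
        donor_only = donor_only + rng.normal(scale=noise_sd, size=wl.size)
        pair = pair + rng.normal(scale=noise_sd, size=wl.size)
    spectra = (
        EmissionSpectrum(wavelengths=wl, intensities=donor_only, label="donor_only"),
        EmissionSpectrum(wavelengths=wl, intensities=pair, label="donor_acceptor"),
    )
    truth = {
        "E_true": E_true,
        "donor_peak": donor_peak,
        "acceptor_peak": acceptor_peak,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return spectra, truth


# ---------------------------------------------------------------------------
# sequences


def gen_sequence_set(
    n: int = 10,
    length: int = 60,
    gc_content: float = 0.5,
    seed: int = 0,
) -> tuple[list[NucleotideSequence], dict[str, Any]]:
    """Random ssDNA sequences with a target GC fraction."""
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_content) / 2,  # A
            gc_content / 2,  # C
            gc_content / 2,  # G
            (1 - gc_content) / 2,  # T
        ]
    )
    seqs = [
        NucleotideSequence(
            id=f"rand{i:03d}",
            bases="".join(rng.choice(list("ACGT"), size=length, p=p)),
        )
        for i in range(n)
    ]
    truth = {"n": n, "length": length, "gc_content": gc_content, "seed": seed}
    return seqs, truth
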