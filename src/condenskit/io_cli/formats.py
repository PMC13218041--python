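"""File formats: FASTA, multi-frame XYZ, fixed-column GRO, and tabular
inputs (topology tables, spectra, melt curves).

Coordinates are nm on disk for both XYZ and GRO (GRO's native unit);
pass ``angstrom=True`` to convert Angstrom input on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from condenskit.cg_metrics.structures import BeadTopology, BeadTrajectory
from condenskit.sequence_design import NucleotideSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_xyz",
    "write_xyz",
    "read_gro",
    "write_gro",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "read_spectrum",
    "read_melt_table",
    "read_table",
]

FASTA_WRAP = 60


class ParseError(ValueError):
    """Raised on malformed input files, with a line number where possible."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTA records; ids from headers up to the first whitespace.

    Lowercase bases are upcased with a warning.
    """
    records: list[NucleotideSequence] = []
    current_id: str | None = None
    chunks: list[str] = []
    saw_lower = False

    def flush(line_no: int) -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        bases = "".join(chunks)
        if not bases:
            raise ParseError(f"empty FASTA record {current_id!r} before line {line_no}")
        records.append(NucleotideSequence(id=current_id, bases=bases))
        current_id, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ParseError(f"line {line_no}: FASTA header has no id")
            else:
                if current_id is None:
                    raise ParseError(f"line {line_no}: sequence data before any header")
                if line != line.upper():
                    saw_lower = True
                chunks.append(line.upper())
        flush(line_no=-1)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if saw_lower:
        warnings.warn(f"{path}: lowercase bases upcased on read", stacklevel=2)
    return records


def write_fasta(path: str | Path, sequences: list[NucleotideSequence]) -> None:
    """Write FASTA with 60-column wrapped sequence lines."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), FASTA_WRAP):
                fh.write(seq.bases[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# XYZ (multi-frame)


def read_xyz(
    path: str | Path,
    frame_spacing_ns: float = 1.0,
    box_edge: float | None = None,
    angstrom: bool = False,
) -> BeadTrajectory:
    """Read a multi-frame XYZ file (coordinates nm unless ``angstrom``)."""
    frames: list[np.ndarray] = []
    n_beads: int | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    line_no = 0
    while i < len(lines):
        header = lines[i].strip()
        line_no = i + 1
        if not header:
            i += 1
            continue
        try:
            count = int(header)
        except ValueError as exc:
            raise ParseError(f"line {line_no}: expected atom count, got {header!r}") from exc
        if n_beads is None:
            n_beads = count
        elif count != n_beads:
            raise ParseError(
                f"line {line_no}: frame has {count} beads, expected {n_beads}"
            )
        coords = np.empty((count, 3))
        for j in range(count):
            idx = i + 2 + j
            if idx >= len(lines):
                raise ParseError(f"line {len(lines)}: truncated frame")
            parts = lines[idx].split()
            if len(parts) < 4:
                raise ParseError(f"line {idx + 1}: expected 'name x y z'")
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"line {idx + 1}: non-numeric coordinate") from exc
        frames.append(coords)
        i += 2 + count
    if not frames:
        raise ParseError(f"{path}: no frames found")
    coords = np.stack(frames)
    if angstrom:
        coords = coords * 0.1
    return BeadTrajectory(
        coords=coords, frame_spacing_ns=frame_spacing_ns, box_edge=box_edge
    )


def write_xyz(
    path: str | Path,
    traj: BeadTrajectory,
    names: np.ndarray | None = None,
    comment: str = "",
) -> None:
    """Write a multi-frame XYZ file in nm."""
    if names is None:
        names = np.array([f"B{i}" for i in range(traj.n_beads)])
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.coords):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f"{comment or 'frame'} {f}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# GRO (fixed-column dialect)


def read_gro(
    path: str | Path,
    frame_spacing_ns: float = 1.0,
) -> tuple[BeadTrajectory, np.ndarray, np.ndarray]:
    """Read a (possibly multi-frame) GRO file.

    Returns (trajectory, residue_indices, bead_names) from the first
    frame's fixed columns; the cubic box edge is taken from the last
    box line when all three edges agree.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[np.ndarray] = []
    residues: np.ndarray | None = None
    names: np.ndarray | None = None
    box_edge: float | None = None
    n_beads: int | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {i + 2}: expected atom count") from exc
        if n_beads is None:
            n_beads = count
        elif count != n_beads:
            raise ParseError(f"line {i + 2}: frame has {count} beads, expected {n_beads}")
        coords = np.empty((count, 3))
        res = np.empty(count, dtype=int)
        nm = np.empty(count, dtype=object)
        for j in range(count):
            line = lines[i + 2 + j]
            try:
                res[j] = int(line[0:5])
                nm[j] = line[10:15].strip()
                coords[j] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {i + 3 + j}: malformed GRO atom line") from exc
        box_parts = lines[i + 2 + count].split()
        if len(box_parts) >= 3:
            bx, by, bz = (float(v) for v in box_parts[:3])
            if bx > 0 and np.isclose(bx, by) and np.isclose(bx, bz):
                box_edge = bx
        frames.append(coords)
        if residues is None:
            residues, names = res, nm
        i += 3 + count
    if not frames:
        raise ParseError(f"{path}: no frames found")
    traj = BeadTrajectory(
        coords=np.stack(frames), frame_spacing_ns=frame_spacing_ns, box_edge=box_edge
    )
    return traj, residues, names


def write_gro(
    path: str | Path,
    traj: BeadTrajectory,
    residues: np.ndarray | None = None,
    names: np.ndarray | None = None,
    resnames: np.ndarray | None = None,
    title: str = "condenskit",
) -> None:
    """Write a multi-frame fixed-column GRO file (nm)."""
    n = traj.n_beads
    if residues is None:
        residues = np.arange(1, n + 1)
    if names is None:
        names = np.array([f"B{i + 1}" for i in range(n)])
    if resnames is None:
        resnames = np.array(["BEAD"] * n)
    edge = traj.box_edge if traj.box_edge is not None else 0.0
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.coords):
            fh.write(f"{title} frame {f}\n")
            fh.write(f"{n:5d}\n")
            for j in range(n):
                fh.write(
                    f"{int(residues[j]) % 100000:5d}{str(resnames[j])[:5]:<5s}"
                    f"{str(names[j])[:5]:>5s}{(j + 1) % 100000:5d}"
                    f"{frame[j, 0]:8.3f}{frame[j, 1]:8.3f}{frame[j, 2]:8.3f}\n"
                )
            fh.write(f"{edge:10.5f}{edge:10.5f}{edge:10.5f}\n")


def read_trajectory(
    path: str | Path, format: str | None = None, **kwargs
) -> BeadTrajectory:
    """Dispatch on trajectory format ('xyz' or 'gro'; inferred from suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_xyz(path, **kwargs)
    if fmt == "gro":
        return read_gro(path, **kwargs)[0]
    raise ValueError(f"unknown trajectory format {fmt!r}; use 'xyz' or 'gro'")


def write_trajectory(path: str | Path, traj: BeadTrajectory, **kwargs) -> None:
    fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        write_xyz(path, traj, **kwargs)
    elif fmt == "gro":
        write_gro(path, traj, **kwargs)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}; use 'xyz' or 'gro'")


# ---------------------------------------------------------------------------
# tables

_TOPOLOGY_COLUMNS = ["bead", "radius", "charge", "sigma", "epsilon", "molecule", "residue"]


def read_topology(path: str | Path) -> BeadTopology:
    """Read a bead topology from a whitespace/TSV table.

    Required columns: bead, radius, charge, sigma, epsilon, molecule,
    residue.
    """
    df = read_table(path)
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: topology table missing columns {missing}")
    return BeadTopology(
        radius=df["radius"].to_numpy(float),
        charge=df["charge"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        epsilon=df["epsilon"].to_numpy(float),
        molecule=df["molecule"].to_numpy(str),
        residue=df["residue"].to_numpy(int),
        name=df["bead"].to_numpy(str),
    )


def write_topology(path: str | Path, top: BeadTopology) -> None:
    pd.DataFrame(
        {
            "bead": top.name,
            "radius": top.radius,
            "charge": top.charge,
            "sigma": top.sigma,
            "epsilon": top.epsilon,
            "molecule": top.molecule,
            "residue": top.residue,
        }
    ).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Delimited table reader: TSV/CSV by suffix, else whitespace."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return pd.read_csv(path)
    if suffix in {".tsv", ".txt"}:
        return pd.read_csv(path, sep="\t")
    return pd.read_csv(path, sep=r"\s+")


def read_spectrum(path: str | Path, label: str = ""):
    """Read a (wavelength, intensity) table into an EmissionSpectrum."""
    from condenskit.spectro_fret import EmissionSpectrum

    df = read_table(path)
    cols = list(df.columns)
    wl_col = next((c for c in cols if c.lower().startswith("wavelength")), cols[0])
    in_col = next((c for c in cols if c.lower().startswith("intensity")), cols[1])
    return EmissionSpectrum(
        wavelengths=df[wl_col].to_numpy(float),
        intensities=df[in_col].to_numpy(float),
        label=label or str(path),
    )


def read_melt_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (temperature, ellipticity) table."""
    df = read_table(path)
    cols = list(df.columns)
    t_col = next((c for c in cols if c.lower().startswith("temp")), cols[0])
    e_col = next((c for c in cols if c.lower().startswith("ellip")), cols[1])
    return df[t_col].to_numpy(float), df[e_col].to_numpy(float)
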