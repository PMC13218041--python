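"""FRET efficiency / Forster-distance calculations and CD renaturation
melting analysis.

Efficiency is computed from donor-only and donor-acceptor emission at a
readout wavelength (default 568 nm) as ``E = 1 - F_DA / F_D``; distance
follows ``d = R0 * ((1 - E) / E)**(1/6)`` with a default Forster distance
of 5.1 nm.  Melting temperatures come from a Boltzmann sigmoid fitted to
renaturation ellipticity, ``y = A2 + (A1 - A2) / (1 + exp((T - Tm)/dT))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EmissionSpectrum",
    "FretMeasurement",
    "MeltFit",
    "DEFAULT_R0_NM",
    "DEFAULT_READOUT_NM",
    "subtract_background",
    "fret_efficiency",
    "fret_distance",
    "efficiency_change",
    "fret_measurement",
    "replicate_distances",
    "boltzmann_melt_fit",
    "relative_ellipticity_change",
]

DEFAULT_R0_NM = 5.1
DEFAULT_READOUT_NM = 568.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.shape != inten.shape:
            raise ValueError("wavelengths and intensities must be equal-length 1-D arrays")
        if wl.size < 1:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)

    def intensity_at(self, wavelength: float, interpolate: bool = False) -> float:
        """Intensity at ``wavelength``: nearest grid point, or linear interpolation."""
        if interpolate:
            return float(np.interp(wavelength, self.wavelengths, self.intensities))
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.intensities[idx])


@dataclass(frozen=True)
class FretMeasurement:
    """Donor intensities, transfer efficiency, and derived distance."""

    F_D: float
    F_DA: float
    E: float
    d: float | None
    R0: float = DEFAULT_R0_NM


@dataclass(frozen=True)
class MeltFit:
    """Boltzmann-sigmoid melt parameters from a renaturation curve.

    ``y = A2 + (A1 - A2) / (1 + exp((T - Tm) / dT))``
    """

    Tm: float
    A1: float
    A2: float
    dT: float
    Tm_stderr: float
    residuals: np.ndarray = field(repr=False)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def predict(self, temps: np.ndarray) -> np.ndarray:
        return _boltzmann(np.asarray(temps, dtype=float), self.A1, self.A2, self.Tm, self.dT)


def subtract_background(
    spec: EmissionSpectrum, background: EmissionSpectrum
) -> EmissionSpectrum:
    """Pointwise background subtraction on an identical wavelength grid."""
    if spec.wavelengths.shape != background.wavelengths.shape or not np.allclose(
        spec.wavelengths, background.wavelengths
    ):
        raise ValueError("wavelength grids differ; cannot subtract background")
    return EmissionSpectrum(
        wavelengths=spec.wavelengths.copy(),
        intensities=spec.intensities - background.intensities,
        label=f"{spec.label}-bgsub",
    )


def fret_efficiency(F_DA: float, F_D: float) -> float:
    """Transfer efficiency ``E = 1 - F_DA / F_D``, clamped to [0, 1].

    Noisy near-zero-transfer samples can give F_DA slightly above F_D;
    the raw negative efficiency is clamped to 0 with a warning.
    """
    if F_D <= 0:
        raise ZeroDivisionError(f"donor-only intensity must be positive, got {F_D}")
    if F_DA < 0:
        raise ValueError(f"donor-acceptor intensity must be >= 0, got {F_DA}")
    E = 1.0 - F_DA / F_D
    if E < 0.0:
        warnings.warn(
            f"F_DA ({F_DA:g}) exceeds F_D ({F_D:g}); clamping efficiency to 0",
            stacklevel=2,
        )
        return 0.0
    return min(E, 1.0)


def fret_distance(E: float, R0: float = DEFAULT_R0_NM) -> float:
    """Donor-acceptor distance ``d = R0 * ((1 - E) / E)**(1/6)`` in nm."""
    if R0 <= 0:
        raise ValueError(f"R0 must be positive, got {R0}")
    if not 0.0 < E < 1.0:
        raise ValueError(
            f"efficiency must lie strictly in (0, 1) for a finite distance, got {E}"
        )
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


def efficiency_change(E_baseline: float, fold: float) -> float:
    """Efficiency increment when a baseline efficiency rises ``fold``-fold.

    ``dE = E_baseline * (fold - 1)``; the implied final efficiency is
    clamped to 1 with a warning if ``E_baseline * fold`` exceeds 1.
    """
    if E_baseline < 0 or fold < 0:
        raise ValueError("baseline efficiency and fold change must be non-negative")
    E_final = E_baseline * fold
    if E_final > 1.0:
        warnings.warn(
            f"implied final efficiency {E_final:g} exceeds 1; clamping", stacklevel=2
        )
        E_final = 1.0
    return E_final - E_baseline


def fret_measurement(
    donor_only: EmissionSpectrum,
    donor_acceptor: EmissionSpectrum,
    readout_nm: float = DEFAULT_READOUT_NM,
    R0: float = DEFAULT_R0_NM,
    interpolate: bool = False,
) -> FretMeasurement:
    """Full efficiency + distance readout from a donor-only / FRET spectrum pair.

    Distance is ``None`` when the clamped efficiency hits 0 or 1 (no
    finite distance).
    """
    F_D = donor_only.intensity_at(readout_nm, interpolate=interpolate)
    F_DA = donor_acceptor.intensity_at(readout_nm, interpolate=interpolate)
    E = fret_efficiency(F_DA, F_D)
    d = fret_distance(E, R0) if 0.0 < E < 1.0 else None
    return FretMeasurement(F_D=F_D, F_DA=F_DA, E=E, d=d, R0=R0)


def replicate_distances(
    efficiencies: np.ndarray, R0: float = DEFAULT_R0_NM
) -> dict[str, float]:
    """Two replicate-averaging conventions for FRET distances.

    Whether a reported mean distance is the mean of per-replicate
    distances or the distance of the mean efficiency is ambiguous for
    spread efficiencies (the conventions differ by a few percent), so
    both are computed and labelled: ``d_mean_of_replicates`` averages
    fret_distance over replicates; ``d_of_mean_E`` evaluates it at the
    mean efficiency.  ``d_sd`` is the per-replicate distance SD.
    """
    E = np.asarray(efficiencies, dtype=float)
    if E.size == 0:
        raise ValueError("no replicate efficiencies given")
    d_each = np.array([fret_distance(e, R0) for e in E])
    return {
        "d_mean_of_replicates": float(np.mean(d_each)),
        "d_of_mean_E": fret_distance(float(np.mean(E)), R0),
        "d_sd": float(np.std(d_each, ddof=1)) if E.size > 1 else 0.0,
        "E_mean": float(np.mean(E)),
        "n": int(E.size),
    }


def _boltzmann(T, A1, A2, Tm, dT):
    return A2 + (A1 - A2) / (1.0 + np.exp((T - Tm) / dT))


def boltzmann_melt_fit(temps: np.ndarray, signal: np.ndarray) -> MeltFit:
    """Least-squares Boltzmann sigmoid fit of ellipticity vs temperature.

    Initialization: plateaus from the first/last 10% of points, Tm from
    the half-amplitude crossing, dT from the 10-90% transition width.
    """
    T = np.asarray(temps, dtype=float)
    y = np.asarray(signal, dtype=float)
    if T.shape != y.shape or T.ndim != 1:
        raise ValueError("temps and signal must be equal-length 1-D arrays")
    if T.size < 6:
        raise ValueError(f"need >= 6 points to fit a sigmoid, got {T.size}")
    order = np.argsort(T)
    T, y = T[order], y[order]

    k = max(1, T.size // 10)
    A1_0 = float(np.mean(y[:k]))
    A2_0 = float(np.mean(y[-k:]))
    amplitude = A2_0 - A1_0
    if abs(amplitude) < 1e-12 * max(1.0, abs(A1_0)):
        raise RuntimeError("signal has no transition (flat data); cannot fit a sigmoid")

    # half-amplitude crossing and 10-90% width, on the low->high plateau axis
    frac = (y - A1_0) / amplitude
    Tm_0 = float(np.interp(0.5, frac, T)) if np.any(frac >= 0.5) else float(np.median(T))
    T10 = float(np.interp(0.1, frac, T))
    T90 = float(np.interp(0.9, frac, T))
    dT_0 = max(abs(T90 - T10) / 4.4, 1e-3)  # logistic 10-90% width is ~4.39*dT

    try:
        popt, pcov = curve_fit(
            _boltzmann,
            T,
            y,
            p0=[A1_0, A2_0, Tm_0, dT_0],
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"Boltzmann melt fit failed to converge: {exc}") from exc
    A1, A2, Tm, dT = popt
    residuals = y - _boltzmann(T, *popt)
    span = float(np.ptp(T))
    if not (T.min() - span <= Tm <= T.max() + span):
        raise RuntimeError(
            f"degenerate fit: Tm = {Tm:.2f} lies far outside the data range"
        )
    Tm_stderr = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return MeltFit(
        Tm=float(Tm), A1=float(A1), A2=float(A2), dT=float(dT),
        Tm_stderr=Tm_stderr, residuals=residuals,
    )


def relative_ellipticity_change(
    temps: np.ndarray, signal: np.ndarray, reference_temp: float = 90.0
) -> float:
    """Percent change of the final ellipticity vs the reference-temperature value.

    ``100 * (I_final - I_ref) / I_ref`` where I_ref is the signal at the
    reference temperature (nearest grid point) and I_final is the signal
    at the last temperature of the series as given.
    """
    T = np.asarray(temps, dtype=float)
    y = np.asarray(signal, dtype=float)
    if T.shape != y.shape or T.size < 2:
        raise ValueError("temps and signal must be equal-length arrays of >= 2 points")
    idx = int(np.argmin(np.abs(T - reference_temp)))
    if not np.isclose(T[idx], reference_temp):
        raise ValueError(f"reference temperature {reference_temp} not present in series")
    I_ref = y[idx]
    if I_ref == 0:
        raise ZeroDivisionError("reference ellipticity is zero")
    I_final = y[-1]
    return float(100.0 * (I_final - I_ref) / I_ref)
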