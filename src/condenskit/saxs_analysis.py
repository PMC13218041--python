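"""Primary small-angle X-ray scattering analytics.

Input curves carry q in inverse Angstrom (instrument convention); derived
lengths are reported in nm and volumes in nm^3.

* ``guinier_fit`` — linear fit of ln I vs q^2 in a low-q window shrunk
  until ``q_max * Rg <= limit`` (default 1.3); yields Rg and I(0).
* ``kratky_transform`` — ``q^2 I(q)`` or the dimensionless
  ``(q Rg)^2 I / I0`` vs ``q Rg`` form.
* ``porod_volume`` — ``V_p = 2 pi^2 I0 / Q`` with the invariant
  ``Q = int q^2 I dq`` evaluated by trapezoid plus a q^-4 Porod tail
  extrapolation beyond the measured range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScatteringCurve",
    "GuinierResult",
    "GuinierError",
    "guinier_fit",
    "kratky_transform",
    "porod_volume",
]

ANGSTROM_TO_NM = 0.1
DEFAULT_QRG_LIMIT = 1.3
REFINE_QRG_LIMIT = 1.6


class GuinierError(RuntimeError):
    """Raised when no valid Guinier window exists."""


@dataclass(frozen=True)
class ScatteringCurve:
    """1-D scattering profile: q (1/Angstrom), I (a.u.), optional sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        if q.ndim != 1 or q.shape != I.shape:
            raise ValueError("q and I must be equal-length 1-D arrays")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if not np.all(np.isfinite(I)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class GuinierResult:
    """Guinier fit output: Rg (nm), I(0), window used, and fit quality.

    ``Rg_linear`` is the plain ln I vs q^2 slope estimate; ``Rg`` adds a
    q^4 curvature refinement within the same window (see guinier_fit).
    """

    Rg: float
    I0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    Rg_linear: float = 0.0

    @property
    def qRg_max(self) -> float:
        """Dimensionless q*Rg at the high edge of the fit window."""
        return self.q_max * self.Rg / ANGSTROM_TO_NM


def guinier_fit(
    curve: ScatteringCurve,
    qRg_limit: float = DEFAULT_QRG_LIMIT,
    min_points: int = 5,
    curvature_correction: bool = True,
) -> GuinierResult:
    """Guinier analysis: Rg and I(0) from the low-q linear regime.

    Fits ``ln I = ln I0 - (Rg^2 / 3) q^2`` starting from the lowest q,
    iteratively dropping the highest-q point until the fitted Rg
    satisfies ``q_max * Rg <= qRg_limit`` (Rg in Angstrom during the
    fit; reported in nm).

    The plain linear fit over a q*Rg <= 1.3 window carries a systematic
    low bias for flexible chains (the next term of the low-q expansion
    is +q^4 Rg^4 / 36 for a Gaussian coil).  With ``curvature_correction``
    (default) the slope is refined by adding a free q^4 term over a
    slightly extended window (q*Rg <= 1.6, where the quadratic expansion
    still holds but more points stabilize the fit under noise), removing
    that bias for both coil-like and globular curves; the uncorrected
    estimate is kept as ``Rg_linear``.
    """
    positive = curve.I > 0
    q = curve.q[positive]
    I = curve.I[positive]
    if q.size < min_points:
        raise GuinierError("too few positive-intensity points for a Guinier fit")

    hi = q.size
    while hi >= min_points:
        qw, Iw = q[:hi], I[:hi]
        slope, intercept = np.polyfit(qw**2, np.log(Iw), 1)
        if slope >= 0:
            # curve rises at low q: not Guinier-like; shrinking cannot fix sign
            raise GuinierError(
                "non-negative Guinier slope (ln I increases with q^2); "
                "curve is not in a Guinier regime"
            )
        Rg_lin_ang = float(np.sqrt(-3.0 * slope))
        if qw[-1] * Rg_lin_ang <= qRg_limit:
            Rg_ang, I0 = Rg_lin_ang, float(np.exp(intercept))
            if curvature_correction:
                mask = q * Rg_lin_ang <= REFINE_QRG_LIMIT
                qr, Ir = q[mask], I[mask]
                if qr.size >= max(min_points, 6):
                    X = np.vander(qr**2, 3, increasing=True)
                    coef, *_ = np.linalg.lstsq(X, np.log(Ir), rcond=None)
                    if coef[1] < 0:
                        Rg_ang = float(np.sqrt(-3.0 * coef[1]))
                        I0 = float(np.exp(coef[0]))
            fitted = intercept + slope * qw**2
            resid = np.log(Iw) - fitted
            ss_tot = float(np.sum((np.log(Iw) - np.mean(np.log(Iw))) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            return GuinierResult(
                Rg=Rg_ang * ANGSTROM_TO_NM,
                I0=I0,
                q_min=float(qw[0]),
                q_max=float(qw[-1]),
                n_points=int(hi),
                r_squared=r2,
                residuals=resid,
                Rg_linear=Rg_lin_ang * ANGSTROM_TO_NM,
            )
        hi -= 1
    raise GuinierError(
        f"Guinier window collapsed below {min_points} points before "
        f"satisfying q*Rg <= {qRg_limit}"
    )


def kratky_transform(
    curve: ScatteringCurve,
    Rg: float | None = None,
    I0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Kratky transform ``(q, q^2 I)``, or dimensionless ``(qRg, (qRg)^2 I/I0)``.

    ``Rg`` is in nm when given (converted internally to the q grid's
    Angstrom units).  Pass both Rg and I0 for the dimensionless form.
    """
    if (Rg is None) != (I0 is None):
        raise ValueError("provide both Rg and I0 for the dimensionless form, or neither")
    if Rg is None:
        return curve.q.copy(), curve.q**2 * curve.I
    Rg_ang = Rg / ANGSTROM_TO_NM
    x = curve.q * Rg_ang
    return x, x**2 * curve.I / I0


def porod_volume(
    curve: ScatteringCurve,
    I0: float,
    tail_fraction: float = 0.5,
) -> float:
    """Porod volume ``V_p = 2 pi^2 I0 / Q`` in nm^3.

    The invariant ``Q = int q^2 I dq`` combines a trapezoid over the
    measured range with a Porod ``K/q^4`` tail beyond q_max, where K is
    the mean of ``q^4 I`` over the last ``tail_fraction`` of the curve
    (averaging over form-factor oscillations).  Warns when the tail term
    dominates the invariant — in particular when the Porod regime
    (q_max * size >> pi) is not reached within the measured range.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    q, I = curve.q, curve.I
    Q_measured = float(np.trapezoid(q**2 * I, q))
    n_tail = max(int(round(tail_fraction * q.size)), 3)
    K = float(np.mean(q[-n_tail:] ** 4 * I[-n_tail:]))
    Q_tail = K / q[-1]  # int_{qmax}^inf K q^-2 dq
    Q = Q_measured + Q_tail
    if Q_tail > 0.3 * Q:
        warnings.warn(
            f"Porod tail extrapolation contributes {Q_tail / Q:.0%} of the "
            "invariant; volume estimate may be unreliable",
            stacklevel=2,
        )
    V_ang3 = 2.0 * np.pi**2 * I0 / Q  # Angstrom^3 since q is 1/Angstrom
    return float(V_ang3 * ANGSTROM_TO_NM**3)
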