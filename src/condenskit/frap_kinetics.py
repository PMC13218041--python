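"""FRAP trace processing: double normalization against a reference ROI and
background, 0-100 rescaling to prebleach, exponential-asymptote recovery
fitting, and half-recovery time extraction.

Processing chain
----------------
1. ``frap_double_normalize``:
   ``I(t) = (I_R1(t) - I_R3(t)) * (I_R2_pre - I_R3_pre) / (I_R2(t) - I_R3(t))``
2. ``frap_minmax_normalize``: ``100 * (I - I_min) / (I_pre - I_min)``
3. ``fit_recovery``: least squares of ``y(t) = a - b * c**t`` with
   ``a > 0``, ``b > 0``, ``0 < c < 1``.
4. ``half_time``: time at which the fitted curve crosses ``y = a/2``.

The published closed form for the half time, ``log_c(1/(2ab))``, is
dimensionally inconsistent with the fit model (it matches the crossing
only when a == 1 in normalized units); the numeric crossing solve is
canonical here and the printed expression is available as
``method="closed_form"`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "FrapTrace",
    "FrapFit",
    "frap_double_normalize",
    "frap_minmax_normalize",
    "fit_recovery",
    "half_time",
    "process_trace",
]


@dataclass(frozen=True)
class FrapTrace:
    """Raw three-channel FRAP time series with prebleach references.

    R1 = bleached ROI, R2 = unbleached reference ROI, R3 = background.
    ``t`` is seconds from the bleach event.
    """

    t: np.ndarray
    I_R1: np.ndarray
    I_R2: np.ndarray
    I_R3: np.ndarray
    I_R1_pre: float
    I_R2_pre: float
    I_R3_pre: float

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "I_R1", "I_R2", "I_R3"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
        n = arrays["t"].size
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.size != n:
                raise ValueError("t, I_R1, I_R2, I_R3 must be equal-length 1-D arrays")
            object.__setattr__(self, name, arr)
        if np.any(arrays["t"] < 0) or np.any(np.diff(arrays["t"]) <= 0):
            raise ValueError("t must be non-negative and strictly increasing")
        for name in ("I_R1_pre", "I_R2_pre", "I_R3_pre"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class FrapFit:
    """Fitted exponential-asymptote recovery ``y(t) = a - b * c**t``."""

    a: float
    b: float
    c: float
    t_half: float
    mobile_fraction: float
    residuals: np.ndarray = field(repr=False)
    degenerate: bool = False

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a - self.b * self.c ** np.asarray(t, dtype=float)


def frap_double_normalize(trace: FrapTrace) -> np.ndarray:
    """Background-subtract and reference-correct the bleached-ROI channel."""
    gap = trace.I_R2 - trace.I_R3
    bad = np.flatnonzero(gap == 0)
    if bad.size:
        raise ZeroDivisionError(
            f"reference and background coincide at t = {trace.t[bad[0]]:g} s; "
            "cannot normalize"
        )
    pre_gap = trace.I_R2_pre - trace.I_R3_pre
    if pre_gap == 0:
        raise ZeroDivisionError("prebleach reference equals prebleach background")
    return (trace.I_R1 - trace.I_R3) * (pre_gap / gap)


def frap_minmax_normalize(
    series: np.ndarray, prebleach: float, i_min: float | None = None
) -> np.ndarray:
    """Rescale so the experiment minimum maps to 0 and prebleach to 100.

    ``i_min`` defaults to the series minimum; pass the raw experiment
    minimum explicitly when it is not contained in the post-bleach window.
    """
    y = np.asarray(series, dtype=float)
    lo = float(np.min(y)) if i_min is None else float(i_min)
    if prebleach <= lo:
        raise ValueError(
            f"degenerate trace: prebleach ({prebleach:g}) does not exceed "
            f"minimum ({lo:g})"
        )
    return 100.0 * (y - lo) / (prebleach - lo)


def _recovery(t, a, b, c):
    return a - b * np.power(c, t)


def fit_recovery(t: np.ndarray, y: np.ndarray) -> FrapFit:
    """Bounded least-squares fit of ``y(t) = a - b * c**t``.

    The asymptote ``a`` doubles as the mobile fraction when ``y`` is in
    percent-of-prebleach units.  A flat, non-recovering trace yields a
    degenerate fit flagged with ``degenerate=True`` and b ~ 0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be equal-length 1-D arrays")
    if t.size < 8:
        raise ValueError(f"need >= 8 points to fit recovery, got {t.size}")

    a0 = float(np.max(y))
    b0 = max(a0 - float(y[0]), 1e-6)
    p0 = [max(a0, 1e-6), b0, 0.9]
    bounds = ([1e-12, 1e-12, 1e-12], [np.inf, np.inf, 1.0 - 1e-12])
    try:
        popt, _ = curve_fit(_recovery, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"recovery fit failed to converge: {exc}") from exc
    a, b, c = (float(v) for v in popt)
    residuals = y - _recovery(t, a, b, c)

    degenerate = False
    amplitude_scale = max(abs(a), float(np.ptp(y)), 1e-12)
    if b < 1e-3 * amplitude_scale:
        degenerate = True
        warnings.warn(
            "trace does not recover (fitted amplitude b ~ 0); fit is degenerate",
            stacklevel=2,
        )
    fit = FrapFit(
        a=a, b=b, c=c, t_half=np.nan, mobile_fraction=a,
        residuals=residuals, degenerate=degenerate,
    )
    t_half = np.nan if degenerate else half_time(fit)
    return FrapFit(
        a=a, b=b, c=c, t_half=t_half, mobile_fraction=a,
        residuals=residuals, degenerate=degenerate,
    )


def half_time(fit: FrapFit, method: str = "numeric") -> float:
    """Time at which the fitted recovery crosses half its asymptote.

    ``numeric`` (canonical) root-solves ``a - b*c**t = a/2``;
    ``closed_form`` evaluates the published expression ``log_c(1/(2ab))``
    verbatim.  If the curve starts above ``a/2`` the crossing is in the
    past and 0 is returned with a warning.
    """
    a, b, c = fit.a, fit.b, fit.c
    if not (0.0 < c < 1.0) or a <= 0 or b < 0:
        raise ValueError(f"invalid fit parameters a={a}, b={b}, c={c}")
    if method == "closed_form":
        return float(np.log(1.0 / (2.0 * a * b)) / np.log(c))
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}; use 'numeric' or 'closed_form'")
    y0 = a - b  # value at t = 0
    if y0 >= a / 2.0:
        if y0 > a / 2.0:
            warnings.warn(
                "recovery already above half-asymptote at t = 0; t_half = 0",
                stacklevel=2,
            )
        return 0.0

    def f(t):
        return a - b * c**t - a / 2.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for 0 < c < 1
            raise RuntimeError("half-crossing bracket expansion failed")
    return float(brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-15))


def process_trace(
    trace: FrapTrace,
    window: float | None = None,
    i_min: float | None = None,
) -> FrapFit:
    """Full pipeline: double normalize, 0-100 rescale, fit recovery.

    ``window`` truncates the analysis to the first ``window`` seconds
    (per-construct analysis windows); default is the full trace.
    """
    processed = frap_double_normalize(trace)
    pre = (trace.I_R1_pre - trace.I_R3_pre)
    normalized = frap_minmax_normalize(processed, prebleach=pre, i_min=i_min)
    t = trace.t
    if window is not None:
        keep = t <= window
        t, normalized = t[keep], normalized[keep]
    return fit_recovery(t, normalized)
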