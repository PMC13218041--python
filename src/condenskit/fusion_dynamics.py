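"""Droplet-fusion relaxation analysis.

Aspect ratios from ellipse axes relax toward 1 as two fused droplets
round up; the decay ``AR(t) = 1 + (AR0 - 1) * exp(-t / tau)`` yields the
characteristic fusion time tau per event, summarized across events and
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FusionEvent",
    "FusionFit",
    "DegenerateFusionError",
    "aspect_ratio_series",
    "trim_precontact",
    "fit_fusion_decay",
    "summarize_tau",
    "TauSummary",
]


class DegenerateFusionError(RuntimeError):
    """Raised when an aspect-ratio series shows no relaxation to fit."""


@dataclass(frozen=True)
class FusionEvent:
    """Time series of ellipse axes (um) and derived aspect ratios for one event."""

    t: np.ndarray
    l_long: np.ndarray
    l_short: np.ndarray
    AR: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ll = np.asarray(self.l_long, dtype=float)
        ls = np.asarray(self.l_short, dtype=float)
        if not (t.shape == ll.shape == ls.shape) or t.ndim != 1:
            raise ValueError("t, l_long, l_short must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "l_long", ll)
        object.__setattr__(self, "l_short", ls)
        object.__setattr__(self, "AR", aspect_ratio_series(ll, ls))


@dataclass(frozen=True)
class FusionFit:
    """Single-exponential aspect-ratio relaxation fit."""

    AR0: float
    tau: float
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return 1.0 + (self.AR0 - 1.0) * np.exp(-np.asarray(t, dtype=float) / self.tau)


@dataclass(frozen=True)
class TauSummary:
    """Per-condition fusion-time statistics."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    ratios: dict[tuple[str, str], float]


def aspect_ratio_series(l_long: np.ndarray, l_short: np.ndarray) -> np.ndarray:
    """Elementwise ``l_long / l_short`` with axis-order robustness.

    Frames where the nominal long axis is shorter than the short axis are
    swapped (with a warning) so AR >= 1 everywhere.
    """
    ll = np.asarray(l_long, dtype=float)
    ls = np.asarray(l_short, dtype=float)
    if ll.shape != ls.shape:
        raise ValueError("axis arrays must have the same shape")
    if np.any(ll <= 0) or np.any(ls <= 0):
        raise ValueError("ellipse axes must be positive")
    swapped = ll < ls
    if np.any(swapped):
        warnings.warn(
            f"{int(np.sum(swapped))} frame(s) had l_long < l_short; axes swapped",
            stacklevel=2,
        )
    return np.maximum(ll, ls) / np.minimum(ll, ls)


def trim_precontact(
    t: np.ndarray, AR: np.ndarray, rezero: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Drop leading frames where AR is undefined (NaN, pre-contact).

    With ``rezero`` the first post-contact frame becomes t = 0.
    """
    t = np.asarray(t, dtype=float)
    AR = np.asarray(AR, dtype=float)
    valid = np.flatnonzero(np.isfinite(AR))
    if valid.size == 0:
        raise ValueError("no post-contact frames (AR is NaN throughout)")
    first = valid[0]
    t_out, ar_out = t[first:], AR[first:]
    if np.any(~np.isfinite(ar_out)):
        raise ValueError("AR has gaps after first contact")
    if rezero:
        t_out = t_out - t_out[0]
    return t_out, ar_out


def _decay(t, AR0, tau):
    return 1.0 + (AR0 - 1.0) * np.exp(-t / tau)


def fit_fusion_decay(t: np.ndarray, AR: np.ndarray) -> FusionFit:
    """Bounded least-squares fit of ``AR(t) = 1 + (AR0 - 1) exp(-t/tau)``.

    AR(inf) is pinned at 1 (full liquid relaxation).  Initialization:
    AR0 from the first frame, tau from the time at which AR - 1 first
    falls below 1/e of its initial excess.
    """
    t = np.asarray(t, dtype=float)
    AR = np.asarray(AR, dtype=float)
    if t.shape != AR.shape or t.ndim != 1:
        raise ValueError("t and AR must be equal-length 1-D arrays")
    if t.size < 6:
        raise ValueError(f"need >= 6 frames to fit a decay, got {t.size}")
    if np.any(AR < 1.0 - 1e-9):
        raise ValueError("aspect ratios must be >= 1")

    excess0 = AR[0] - 1.0
    if float(np.max(AR)) - 1.0 < 1e-9:
        raise DegenerateFusionError("AR is 1 throughout; no fusion relaxation to fit")
    below = np.flatnonzero(AR - 1.0 <= excess0 / np.e)
    tau0 = float(t[below[0]] - t[0]) if below.size and below[0] > 0 else float(
        max(t[-1] - t[0], 1e-6) / 3.0
    )
    tau0 = max(tau0, 1e-6)
    p0 = [max(AR[0], 1.0 + 1e-6), tau0]
    try:
        popt, _ = curve_fit(
            _decay, t, AR, p0=p0,
            bounds=([1.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"fusion decay fit failed to converge: {exc}") from exc
    AR0, tau = (float(v) for v in popt)
    rss = float(np.sum((AR - _decay(t, AR0, tau)) ** 2))
    return FusionFit(AR0=AR0, tau=tau, rss=rss)


def summarize_tau(
    fits: "Mapping[str, Sequence[FusionFit]] | Sequence[FusionFit]",
    ratio_pairs: Sequence[tuple[str, str]] = (),
) -> TauSummary:
    """Mean/SD of tau per condition plus ratios of means between conditions.

    ``fits`` may be a flat sequence (condition name ``"all"``) or a
    mapping from condition name to that condition's event fits.  SD uses
    the sample convention (ddof=1) and is 0 for a single event.
    """
    if not isinstance(fits, Mapping):
        fits = {"all": list(fits)}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n: dict[str, int] = {}
    for cond, cond_fits in fits.items():
        taus = np.array([f.tau for f in cond_fits], dtype=float)
        if taus.size == 0:
            raise ValueError(f"condition {cond!r} has no fusion fits")
        mean[cond] = float(np.mean(taus))
        sd[cond] = float(np.std(taus, ddof=1)) if taus.size > 1 else 0.0
        n[cond] = int(taus.size)
    ratios: dict[tuple[str, str], float] = {}
    for a, b in ratio_pairs:
        if a not in mean or b not in mean:
            raise KeyError(f"ratio pair ({a!r}, {b!r}) names an unknown condition")
        ratios[(a, b)] = mean[a] / mean[b]
    return TauSummary(mean=mean, sd=sd, n=n, ratios=ratios)
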