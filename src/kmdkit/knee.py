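"""Knee ("point of diminishing returns") detection for concave curves.

Implements the kneedle procedure: min-max normalize the curve to the unit
square, form the difference curve d(x) = y_norm(x) - x_norm(x), and report
the knee at its (thresholded) local maximum.  For the smooth, noiseless
Michaelis-Menten curves produced in this package the knee is simply the
global argmax of d, and the continuous limit has the closed form

    knee = sqrt(Km * (Km + Smax)) - Km

on the window [0, Smax] — notably independent of Vmax, which cancels in the
y-normalization.  The knee is NOT scale-invariant: it moves with the window
edge Smax, which is why a Vmax-fraction anchor (90% or 95% of Vmax) must be
stated alongside any knee value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mm_kinetics import mm_rate, MMParams

__all__ = ["KneeResult", "kneedle", "closed_form_mm_knee", "mm_knee"]

DEFAULT_GRID_POINTS = 10001


@dataclass(frozen=True)
class KneeResult:
    """Knee location of a Michaelis-Menten curve over a stated window."""

    knee_x: float
    knee_y: float
    smax: float
    fraction: float | None
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.knee_x < self.smax):
            raise ValueError(
                f"knee_x must lie strictly inside (0, smax); got {self.knee_x} with smax={self.smax}"
            )


def kneedle(x, y, sensitivity: float = 1.0) -> float:
    """Knee x-value of a concave-increasing curve via the kneedle algorithm.

    Both axes are min-max normalized to [0, 1]; the knee is the x at the
    thresholded local maximum of the difference curve d = y_norm - x_norm.
    For a smooth noiseless concave curve this reduces to argmax(d).

    Raises ValueError for flat curves (no y range), non-monotone x, fewer
    than 4 points, or when no knee exists (e.g. a straight line, whose
    difference curve is identically zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError("kneedle requires at least 4 points")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    y_range = y.max() - y.min()
    if y_range == 0.0:
        raise ValueError("flat curve: y has no range, no knee exists")

    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y.min()) / y_range
    d = yn - xn

    # local maxima of the difference curve
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    lmx = np.flatnonzero(interior) + 1
    eps = 1e-12
    lmx = lmx[d[lmx] > eps]
    if lmx.size == 0:
        raise ValueError("no knee found: difference curve has no positive local maximum")

    # Satopaa threshold: a local maximum is a knee if d drops below
    # T = d_lmx - sensitivity * mean spacing before the next local maximum.
    mean_dx = float(np.mean(np.diff(xn)))
    for k, i in enumerate(lmx):
        threshold = d[i] - sensitivity * mean_dx
        j_end = lmx[k + 1] if k + 1 < lmx.size else d.size
        if np.any(d[i + 1 : j_end] < threshold) or j_end == d.size:
            return float(x[i])
    return float(x[lmx[-1]])


def closed_form_mm_knee(km: float, smax: float) -> float:
    """Continuous-limit kneedle knee of v = Vmax*S/(Km+S) on [0, Smax].

    Maximizing the normalized difference curve analytically gives
    knee = sqrt(Km*(Km+Smax)) - Km, independent of Vmax.
    """
    if km <= 0 or smax <= 0:
        raise ValueError("km and smax must be > 0")
    return float(np.sqrt(km * (km + smax)) - km)


def mm_knee(
    km: float,
    smax: float,
    vmax: float = 1.0,
    fraction: float | None = None,
    method: str = "discrete-kneedle",
    n_grid: int = DEFAULT_GRID_POINTS,
) -> KneeResult:
    """Knee of the Michaelis-Menten curve with the given Km over [0, smax].

    ``vmax`` is accepted for interface fidelity but has no effect on the knee
    location (it cancels in the y-normalization); it only scales ``knee_y``.
    ``method`` selects the discrete kneedle on an ``n_grid``-point uniform
    grid (reported at the grid argmax, no sub-grid interpolation) or the
    exact closed form.
    """
    if method not in ("discrete-kneedle", "closed-form"):
        raise ValueError(f"unknown method {method!r}")
    params = MMParams(vmax=vmax, km=km)
    if method == "closed-form":
        kx = closed_form_mm_knee(km, smax)
    else:
        s = np.linspace(0.0, smax, n_grid)
        kx = kneedle(s, mm_rate(s, params))
    return KneeResult(
        knee_x=kx,
        knee_y=float(mm_rate(kx, params)),
        smax=float(smax),
        fraction=fraction,
        method=method,
    )
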