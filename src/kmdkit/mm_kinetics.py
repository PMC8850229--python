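"""Michaelis-Menten saturation kinetics for single-compartment elimination.

The system-wide elimination of a chemical from blood is modelled as a single
saturable process,

    dC/dt = -Vmax * C / (Km + C),

where ``C`` is the blood concentration (mg/dL), ``Vmax`` the asymptotic
maximum elimination rate (mg/dL per hour) and ``Km`` the concentration at
half-maximal rate (mg/dL).  At concentrations well above Km elimination is
near zero-order (constant rate ~ Vmax); well below Km it is first-order with
rate constant Vmax/Km.

This module provides the rate law, the algebra for fractional-Vmax
concentrations, a numeric ODE simulation of the elimination curve, and the
exact Lambert-W closed form of the same curve, which serves both as an oracle
for the solver and as the fast likelihood path for fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import lambertw

__all__ = [
    "MMParams",
    "ConcentrationSeries",
    "mm_rate",
    "conc_at_fraction",
    "simulate_elimination",
    "analytic_concentration",
    "elimination_span",
    "interval_slopes",
]

# exp(g) overflows double precision near g = 709; switch to the asymptotic
# branch of W0 well before that.
_WEXP_ASYMPTOTIC = 700.0
_WEXP_UNDERFLOW = -745.0


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameter pair.

    Attributes
    ----------
    vmax : float
        Maximum elimination rate, in concentration units per hour.
    km : float
        Concentration at half-maximal rate, mg/dL.
    """

    vmax: float
    km: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.vmax) and self.vmax > 0):
            raise ValueError(f"vmax must be finite and > 0, got {self.vmax}")
        if not (np.isfinite(self.km) and self.km > 0):
            raise ValueError(f"km must be finite and > 0, got {self.km}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """An elimination time-concentration series (hours, mg/dL)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size or t.size == 0:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValueError("times and concentrations must be finite")
        if t[0] < 0:
            raise ValueError("first time point must be >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return self.times.size


def mm_rate(s, params: MMParams):
    """Michaelis-Menten rate v = Vmax*s/(Km+s) at concentration(s) ``s``.

    Strictly increasing in ``s`` and bounded above by ``Vmax``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("concentration must be non-negative")
    out = params.vmax * s / (params.km + s)
    return float(out) if out.ndim == 0 else out


def conc_at_fraction(fraction: float, km: float) -> float:
    """Concentration at which the rate equals ``fraction`` of Vmax.

    Solving v = f*Vmax in the rate law gives S = f*Km/(1-f): the 95%-of-Vmax
    concentration is 19*Km and the 90% one is 9*Km, independent of Vmax.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if not (np.isfinite(km) and km > 0):
        raise ValueError(f"km must be finite and > 0, got {km}")
    return fraction * km / (1.0 - fraction)


def _wexp(g: np.ndarray) -> np.ndarray:
    """W0(exp(g)) evaluated stably for any real g.

    For moderate g uses scipy's Lambert W directly; for large g, where exp(g)
    overflows, uses the asymptotic start w = g - log(g) refined by Newton on
    f(w) = w + log(w) - g (three steps reach machine precision).
    """
    g = np.asarray(g, dtype=float)
    out = np.empty_like(g)
    small = g < _WEXP_ASYMPTOTIC
    if small.any():
        out[small] = np.real(lambertw(np.exp(g[small])))
    if (~small).any():
        gg = g[~small]
        w = gg - np.log(gg)
        for _ in range(3):
            w = w - (w + np.log(w) - gg) / (1.0 + 1.0 / w)
        out[~small] = w
    return out


def analytic_concentration(c0: float, params: MMParams, t):
    """Exact solution of dC/dt = -Vmax*C/(Km+C) from C(0)=c0.

    Separating the ODE gives the implicit integrated form
    C + Km*ln C = c0 + Km*ln c0 - Vmax*t, whose explicit solution is

        C(t) = Km * W0( (c0/Km) * exp((c0 - Vmax*t)/Km) )

    with W0 the principal Lambert-W branch.  The argument is handled in log
    space so large c0/Km never overflows.  If the argument underflows to zero
    the concentration is below double precision; 0 is returned with a warning.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if c0 < 0:
        raise ValueError("c0 must be non-negative")
    if c0 == 0.0:
        out = np.zeros_like(t)
        return float(out[0]) if scalar else out
    g = c0 / params.km + np.log(c0 / params.km) - params.vmax * t / params.km
    under = g < _WEXP_UNDERFLOW
    out = np.empty_like(g)
    if under.any():
        warnings.warn(
            "concentration underflowed double precision; clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out[under] = 0.0
    ok = ~under
    out[ok] = params.km * _wexp(g[ok])
    return float(out[0]) if scalar else out


def elimination_span(params: MMParams, c0: float, remaining: float = 0.01) -> float:
    """Time for the concentration to fall to ``remaining``*c0 (hours).

    From the implicit integrated rate law:
    t = (c0 - c_end + Km*ln(c0/c_end)) / Vmax.  Useful for choosing a
    sampling window that covers the whole elimination phase.
    """
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    if not (0.0 < remaining < 1.0):
        raise ValueError("remaining must lie in (0, 1)")
    c_end = remaining * c0
    return (c0 - c_end + params.km * np.log(c0 / c_end)) / params.vmax


def simulate_elimination(c0: float, params: MMParams, times) -> ConcentrationSeries:
    """Numerically integrate the elimination ODE and evaluate at ``times``.

    Uses LSODA (stiff-capable, adaptive) at rtol = atol = 1e-9.  Tiny negative
    values from solver noise are clamped to 0 (the exact solution never
    crosses zero).
    """
    times = np.asarray(times, dtype=float)
    if c0 < 0:
        raise ValueError("c0 must be non-negative")
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if c0 == 0.0:
        return ConcentrationSeries(times, np.zeros_like(times))

    def rhs(t, c):
        return -params.vmax * c / (params.km + c)

    t_end = times[-1]
    if t_end == 0.0:
        return ConcentrationSeries(times, np.full_like(times, c0))
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [c0],
        t_eval=times,
        method="LSODA",
        rtol=1e-9,
        atol=1e-9,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed: {sol.message} "
            f"(vmax={params.vmax}, km={params.km}, c0={c0}, t_end={t_end})"
        )
    conc = np.clip(sol.y[0], 0.0, None)
    return ConcentrationSeries(times, conc)


def interval_slopes(series: ConcentrationSeries, dt: float):
    """Mean slopes (C(t+dt) - C(t))/dt over consecutive intervals of width dt.

    The series must be sampled on a grid containing the interval endpoints
    t0, t0+dt, t0+2*dt, ...; otherwise a ValueError is raised.

    Returns a list of ((t_start, t_end), slope) pairs.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = series.times
    c = series.concentrations
    tol = 1e-9 * max(1.0, dt)
    edges = [0]
    target = t[0] + dt
    i = 1
    while target <= t[-1] + tol:
        j = int(np.searchsorted(t, target - tol))
        if j >= t.size or abs(t[j] - target) > tol:
            raise ValueError(
                f"series grid does not contain t = {target:g}; "
                f"dt = {dt:g} is not commensurate with the sampling grid"
            )
        edges.append(j)
        target += dt
        i += 1
    if len(edges) < 2:
        raise ValueError("series too short for one interval of width dt")
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        slope = (c[b] - c[a]) / (t[b] - t[a])
        out.append(((float(t[a]), float(t[b])), float(slope)))
    return out
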