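"""Assemble the kinetically derived maximum dose (KMD) region.

The KMD is reported as a region, not a point: the Michaelis-Menten rate curve
approaches its asymptote gradually, so there is no single concentration where
kinetics "break".  The region is built from the posterior of Km:

* lower bound  — knee of the MM curve with Km at its posterior 2.5% bound,
  over the window [0, S90] where S90 = 9 * Km_anchor (the 90%-of-Vmax
  concentration);
* upper bound  — knee with Km at its posterior 97.5% bound over [0, S95],
  S95 = 19 * Km_anchor;
* midpoint     — knee with the posterior mean Km over [0, (S90 + S95)/2].

Km_anchor defaults to the posterior mean Km (the truth is unknown on real
data) and can be overridden, e.g. with a known true Km, to reproduce
published anchors exactly.  Knee locations do not depend on Vmax (it cancels
in the kneedle normalization), so only the Km posterior enters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bayes_fit import PosteriorSummary
from .knee import DEFAULT_GRID_POINTS, mm_knee
from .mm_kinetics import conc_at_fraction

__all__ = ["KMDRegion", "compute_kmd_region", "kmd_report", "region_from_report", "format_report"]


@dataclass(frozen=True)
class KMDRegion:
    """KMD region in concentration units (mg/dL)."""

    lower: float
    midpoint: float
    upper: float
    fraction_low: float
    fraction_high: float
    smax_low: float
    smax_high: float
    provenance: dict

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.midpoint < self.upper):
            raise ValueError(
                f"KMD bounds must satisfy 0 < lower < midpoint < upper; got "
                f"({self.lower}, {self.midpoint}, {self.upper})"
            )

    def rounded(self) -> tuple:
        """Bounds rounded to the nearest integer mg/dL."""
        return (
            int(round(self.lower)),
            int(round(self.midpoint)),
            int(round(self.upper)),
        )


def compute_kmd_region(
    posterior: PosteriorSummary,
    fractions: tuple = (0.90, 0.95),
    smax_km: float | None = None,
    method: str = "discrete-kneedle",
    n_grid: int = DEFAULT_GRID_POINTS,
    force: bool = False,
) -> KMDRegion:
    """KMD region from a Km posterior summary.

    ``fractions`` are the Vmax fractions anchoring the evaluation windows
    (strictly increasing, each in (0,1)).  ``smax_km`` is the Km used to
    compute the window anchors; default is the posterior mean Km.  A
    non-converged posterior is refused unless ``force`` is set.
    """
    if not posterior.converged and not force:
        raise ValueError(
            "posterior did not converge (some R-hat > 1.01); refusing to compute "
            "a KMD region from it. Re-run the fit with more draws, or pass "
            "force=True to override."
        )
    f_low, f_high = fractions
    if not (0 < f_low < f_high < 1):
        raise ValueError("fractions must be strictly increasing and within (0, 1)")
    if "km" not in posterior.mean:
        raise ValueError("posterior summary lacks a Km marginal")

    km_mean = posterior.mean["km"]
    km_lo = posterior.ci_lower["km"]
    km_hi = posterior.ci_upper["km"]
    anchor_km = km_mean if smax_km is None else float(smax_km)

    smax_low = conc_at_fraction(f_low, anchor_km)
    smax_high = conc_at_fraction(f_high, anchor_km)
    smax_mid = 0.5 * (smax_low + smax_high)

    k_lower = mm_knee(km_lo, smax_low, fraction=f_low, method=method, n_grid=n_grid)
    k_mid = mm_knee(km_mean, smax_mid, method=method, n_grid=n_grid)
    k_upper = mm_knee(km_hi, smax_high, fraction=f_high, method=method, n_grid=n_grid)

    return KMDRegion(
        lower=k_lower.knee_x,
        midpoint=k_mid.knee_x,
        upper=k_upper.knee_x,
        fraction_low=f_low,
        fraction_high=f_high,
        smax_low=smax_low,
        smax_high=smax_high,
        provenance={
            "anchor_km": anchor_km,
            "lower": {"km": km_lo, "smax": smax_low},
            "midpoint": {"km": km_mean, "smax": smax_mid},
            "upper": {"km": km_hi, "smax": smax_high},
            "method": method,
            "n_grid": n_grid,
        },
    )


def kmd_report(region: KMDRegion, posterior: PosteriorSummary) -> dict:
    """JSON-serializable report: rounded and raw bounds, window anchors,
    posterior marginals with diagnostics, and the settings used."""
    lo, mid, hi = region.rounded()
    return {
        "kmd": {"lower": lo, "midpoint": mid, "upper": hi, "units": "mg/dL"},
        "raw": {"lower": region.lower, "midpoint": region.midpoint, "upper": region.upper},
        "anchors": {
            "smax_low": region.smax_low,
            "smax_high": region.smax_high,
            "fraction_low": region.fraction_low,
            "fraction_high": region.fraction_high,
        },
        "posterior": posterior.to_dict(),
        "settings": region.provenance,
    }


def region_from_report(report: dict) -> KMDRegion:
    """Reconstruct the KMDRegion from a report dict (round-trip inverse)."""
    raw = report["raw"]
    anchors = report["anchors"]
    return KMDRegion(
        lower=raw["lower"],
        midpoint=raw["midpoint"],
        upper=raw["upper"],
        fraction_low=anchors["fraction_low"],
        fraction_high=anchors["fraction_high"],
        smax_low=anchors["smax_low"],
        smax_high=anchors["smax_high"],
        provenance=report["settings"],
    )


def format_report(report: dict) -> str:
    """Human-readable one-screen summary of a KMD report."""
    k = report["kmd"]
    raw = report["raw"]
    a = report["anchors"]
    lines = [
        "KMD region (knee of the system-wide Michaelis-Menten curve)",
        f"  lower    : {k['lower']:>4d} mg/dL  (raw {raw['lower']:.2f}, window 0-{a['smax_low']:.1f})",
        f"  midpoint : {k['midpoint']:>4d} mg/dL  (raw {raw['midpoint']:.2f})",
        f"  upper    : {k['upper']:>4d} mg/dL  (raw {raw['upper']:.2f}, window 0-{a['smax_high']:.1f})",
        f"  window anchors at {a['fraction_low']:.0%} and {a['fraction_high']:.0%} of Vmax",
        "posterior marginals:",
    ]
    for p, s in report["posterior"].items():
        if not isinstance(s, dict) or "mean" not in s:
            continue
        rhat = s.get("rhat")
        rhat_s = f", rhat {rhat:.3f}" if rhat is not None and np.isfinite(rhat) else ""
        lines.append(
            f"  {p:>5s}: mean {s['mean']:.2f}, 95% CI [{s['ci95'][0]:.2f}, {s['ci95'][1]:.2f}]{rhat_s}"
        )
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
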