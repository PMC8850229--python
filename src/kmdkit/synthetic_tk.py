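"""Synthetic toxicokinetic datasets with known ground truth.

Generates single-compartment saturable-elimination time courses from chosen
(Vmax, Km, c0), with configurable observation noise, so that the whole
fit-then-find-the-knee pipeline can be exercised and validated without any
external data.  The noiseless curve is the exact Lambert-W solution of the
elimination ODE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mm_kinetics import (
    ConcentrationSeries,
    MMParams,
    analytic_concentration,
    conc_at_fraction,
    elimination_span,
)

__all__ = [
    "NoiseModel",
    "TKDataset",
    "generate_tk_dataset",
    "default_example_dataset",
    "read_tk_csv",
]

CSV_HEADER = ("time_h", "conc_mg_dl")

_NOISE_KINDS = ("none", "additive-gaussian", "proportional-gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise specification.

    kind
        ``"none"``, ``"additive-gaussian"`` (scale = sd in mg/dL) or
        ``"proportional-gaussian"`` (scale = coefficient of variation).
    scale
        Noise magnitude; ignored for ``kind="none"``.
    """

    kind: str = "none"
    scale: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")


@dataclass(frozen=True)
class TKDataset:
    """A toxicokinetic elimination series plus provenance metadata.

    ``truth`` and ``c0_true`` are present for synthetic data and absent
    (None) for user-supplied measurements.
    """

    series: ConcentrationSeries
    truth: MMParams | None = None
    c0_true: float | None = None
    units: dict = field(default_factory=lambda: {"time": "h", "conc": "mg/dL"})
    seed: int | None = None
    noise: NoiseModel | None = None

    @property
    def times(self) -> np.ndarray:
        return self.series.times

    @property
    def concentrations(self) -> np.ndarray:
        return self.series.concentrations

    def __len__(self) -> int:
        return len(self.series)

    def write_csv(self, path, sidecar: bool = True) -> None:
        """Write ``time_h,conc_mg_dl`` CSV; truth and seed go to a sidecar JSON."""
        path = Path(path)
        df = pd.DataFrame(
            {CSV_HEADER[0]: self.series.times, CSV_HEADER[1]: self.series.concentrations}
        )
        df.to_csv(path, index=False)
        if sidecar:
            meta: dict = {"units": self.units}
            if self.truth is not None:
                meta["truth"] = {
                    "vmax": self.truth.vmax,
                    "km": self.truth.km,
                    "c0": self.c0_true,
                }
            if self.seed is not None:
                meta["seed"] = self.seed
            if self.noise is not None:
                meta["noise"] = {"kind": self.noise.kind, "scale": self.noise.scale}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_tk_csv(path) -> TKDataset:
    """Read a ``time_h,conc_mg_dl`` CSV (and its sidecar JSON if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} is missing required column(s) {missing}; header must be {','.join(CSV_HEADER)}")
    series = ConcentrationSeries(
        df[CSV_HEADER[0]].to_numpy(float), df[CSV_HEADER[1]].to_numpy(float)
    )
    truth = None
    c0 = None
    seed = None
    noise = None
    units = {"time": "h", "conc": "mg/dL"}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        units = meta.get("units", units)
        if "truth" in meta:
            truth = MMParams(meta["truth"]["vmax"], meta["truth"]["km"])
            c0 = meta["truth"].get("c0")
        seed = meta.get("seed")
        if "noise" in meta:
            noise = NoiseModel(meta["noise"]["kind"], meta["noise"]["scale"])
    return TKDataset(series, truth=truth, c0_true=c0, units=units, seed=seed, noise=noise)


def _apply_noise(clean: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none":
        return clean.copy()
    z = rng.standard_normal(clean.size)
    if noise.kind == "additive-gaussian":
        noisy = clean + noise.scale * z
    else:  # proportional-gaussian
        noisy = clean * (1.0 + noise.scale * z)
    # negative draws are physically impossible readings; truncate at zero
    return np.clip(noisy, 0.0, None)


def generate_tk_dataset(
    params: MMParams,
    c0: float,
    times,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> TKDataset:
    """Simulate an elimination time course and add observation noise.

    The noiseless curve is the exact Lambert-W solution of
    dC/dt = -Vmax*C/(Km+C); identical (params, c0, times, noise, seed) give
    identical output.
    """
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    noise = noise or NoiseModel()
    if seed is not None and not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer or None, got {type(seed).__name__}")
    if noise.kind != "none" and seed is None:
        raise ValueError("a seed is required when generating noisy data")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    clean = analytic_concentration(c0, params, times)
    rng = np.random.default_rng(seed)
    conc = _apply_noise(np.atleast_1d(clean), noise, rng)
    return TKDataset(
        ConcentrationSeries(times, conc),
        truth=params,
        c0_true=float(c0),
        seed=seed,
        noise=noise,
    )


# Worked-example ground truth: liver alcohol dehydrogenase kinetics.
EXAMPLE_PARAMS = MMParams(vmax=175.0, km=11.8)
EXAMPLE_N_POINTS = 49
EXAMPLE_CV = 0.05


def default_example_dataset(seed: int, noise: NoiseModel | None = None) -> TKDataset:
    """The packaged alcohol-elimination example dataset.

    Truth Vmax = 175, Km = 11.8 mg/dL; starting concentration c0 = 19*Km =
    224.2 mg/dL (the 95%-of-Vmax anchor); 49 samples uniformly spanning the
    elimination phase (time zero to 99% elimination, ~1.58 h); proportional
    Gaussian noise with CV = 5% unless overridden.
    """
    c0 = conc_at_fraction(0.95, EXAMPLE_PARAMS.km)
    span = elimination_span(EXAMPLE_PARAMS, c0, remaining=0.01)
    times = np.linspace(0.0, span, EXAMPLE_N_POINTS)
    if noise is None:
        noise = NoiseModel("proportional-gaussian", EXAMPLE_CV)
    return generate_tk_dataset(EXAMPLE_PARAMS, c0, times, noise=noise, seed=seed)
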