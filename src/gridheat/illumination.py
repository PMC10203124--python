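"""Incident illumination profiles.

The excitation laser illuminates a circular field (119 µm diameter in the
reference instrument) with either a uniform profile or an "offset Gaussian":
a Gaussian bump of width σ on a flat baseline b,

    I(r) = P · [ b + (1 − b) · exp(−r² / 2σ²) ],

where P is the peak power density in W/cm².  Power densities are carried in
W/cm² throughout (the field's unit); lengths in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ParameterError

__all__ = ["BeamProfile", "sigma_from_drop", "intensity_at", "intensity_map"]


@dataclass(frozen=True)
class BeamProfile:
    """Illumination profile over the sample plane.

    ``kind`` is ``"uniform"`` (constant ``peak_density_P`` everywhere) or
    ``"offset_gaussian"``.  ``center_offset`` positions the beam centre
    relative to the grid-square centre.
    """

    kind: str = "uniform"
    peak_density_P: float = 0.0  # W/cm²
    sigma: Optional[float] = None  # µm
    baseline_fraction_b: float = 0.0
    field_diameter: float = 119.0  # µm
    center_offset: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "offset_gaussian"):
            raise ParameterError(f"unknown beam kind {self.kind!r}")
        if self.peak_density_P < 0:
            raise ParameterError("peak power density must be non-negative")
        if self.kind == "offset_gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ParameterError("offset_gaussian requires sigma > 0")
            if not 0.0 <= self.baseline_fraction_b < 1.0:
                raise ParameterError("baseline fraction must lie in [0, 1)")

    @classmethod
    def from_config(cls, cfg: dict) -> "BeamProfile":
        """Build a beam from a config mapping (YAML/JSON keys).

        Recognised keys: kind, P_W_cm2, sigma_um OR (drop_fraction,
        drop_radius_um), baseline_fraction, field_diameter_um,
        center_offset_um.
        """
        kind = cfg.get("kind", "uniform")
        b = float(cfg.get("baseline_fraction", 0.0))
        sigma = cfg.get("sigma_um")
        if kind == "offset_gaussian" and sigma is None:
            sigma = sigma_from_drop(
                float(cfg["drop_fraction"]), float(cfg["drop_radius_um"]), b
            )
        offset = tuple(cfg.get("center_offset_um", (0.0, 0.0)))
        return cls(
            kind=kind,
            peak_density_P=float(cfg.get("P_W_cm2", 0.0)),
            sigma=None if sigma is None else float(sigma),
            baseline_fraction_b=b,
            field_diameter=float(cfg.get("field_diameter_um", 119.0)),
            center_offset=offset,
        )


def sigma_from_drop(drop_fraction: float, radius: float, baseline_fraction_b: float = 0.0) -> float:
    """Gaussian width σ from a stated intensity drop at a stated radius.

    Solves b + (1 − b)·exp(−r²/2σ²) = 1 − drop at r = radius.  The reference
    instrument's "27 % drop at 45 µm" (b = 0) gives σ ≈ 56.7 µm.
    """
    b = baseline_fraction_b
    if not 0.0 <= b < 1.0:
        raise ParameterError("baseline fraction must lie in [0, 1)")
    if not 0.0 < drop_fraction < 1.0 - b:
        raise ParameterError(
            f"drop fraction must lie in (0, {1 - b:g}) to be reachable above the baseline"
        )
    if radius <= 0:
        raise ParameterError("radius must be positive")
    # exp(−r²/2σ²) = (1 − drop − b)/(1 − b)
    ratio = (1.0 - drop_fraction - b) / (1.0 - b)
    return radius / math.sqrt(2.0 * math.log(1.0 / ratio))


def intensity_at(beam: BeamProfile, r: np.ndarray | float) -> np.ndarray | float:
    """Local power density (W/cm²) at radial distance r (µm) from beam centre."""
    if beam.kind == "uniform":
        return beam.peak_density_P * np.ones_like(np.asarray(r, dtype=float))
    b = beam.baseline_fraction_b
    r = np.asarray(r, dtype=float)
    return beam.peak_density_P * (b + (1.0 - b) * np.exp(-(r**2) / (2.0 * beam.sigma**2)))


def intensity_map(
    beam: BeamProfile,
    L: float,
    resolution: float,
    Ly: Optional[float] = None,
) -> np.ndarray:
    """Raster of local power density over an L×L (or L×Ly) grid square.

    Pixels are sampled at their centres ((i+0.5)/resolution from the square
    corner); the beam centre sits at the square centre plus
    ``beam.center_offset``.  A uniform beam yields a constant raster.
    """
    Lx = L
    Ly = L if Ly is None else Ly
    nx = int(round(Lx * resolution))
    ny = int(round(Ly * resolution))
    if beam.kind == "uniform":
        return np.full((ny, nx), beam.peak_density_P, dtype=float)
    x = (np.arange(nx) + 0.5) / resolution - (Lx / 2.0 + beam.center_offset[0])
    y = (np.arange(ny) + 0.5) / resolution - (Ly / 2.0 + beam.center_offset[1])
    xx, yy = np.meshgrid(x, y)
    return intensity_at(beam, np.sqrt(xx**2 + yy**2))
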