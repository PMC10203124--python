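"""Support-grid and holey-film geometry.

A TEM support grid is a metal mesh (200/300/400 squares per inch) carrying a
thin support film.  Holey films are perforated by a regular lattice of holes,
named "d/s" for d µm holes separated by s µm of film (so a "2/1" film has
2 µm holes on a 3 µm pitch).  The carbon area fraction η_c — the fraction of
the film plane that is material rather than hole — controls how much light
the film absorbs per unit illuminated area and therefore how strongly it
heats under the excitation laser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GeometryError

__all__ = [
    "HoleyFilmPattern",
    "FilmMaterial",
    "GridSpec",
    "carbon_area_fraction",
    "square_size_from_mesh",
    "film_mask",
    "film_mask_at",
    "MESH_SQUARE_SIZE_UM",
    "DEFAULT_BAR_WIDTH_UM",
]

#: Grid-square sizes (µm) for the standard meshes.  These printed values take
#: precedence over the inch-pitch formula; the 200-mesh entry implies a wider
#: bar than the 300/400 entries do, so no single bar width reproduces all three.
MESH_SQUARE_SIZE_UM = {200: 90.0, 300: 58.0, 400: 37.0}

#: Default bar width (µm) for non-standard meshes, consistent with the 300-
#: and 400-mesh square sizes (25400/300 − 58 ≈ 26.7, 25400/400 − 37 = 26.5).
DEFAULT_BAR_WIDTH_UM = 26.5

MICRONS_PER_INCH = 25400.0


@dataclass(frozen=True)
class HoleyFilmPattern:
    """Hole pattern of a support film.

    Parameters
    ----------
    hole_diameter : float
        Hole diameter d in µm (ignored for continuous film).
    hole_spacing : float
        Edge-to-edge gap s between adjacent holes in µm, so the lattice
        pitch is d + s.
    lattice : {"square", "none"}
        ``"none"`` denotes a continuous (hole-free) film.
    """

    hole_diameter: float = 0.0
    hole_spacing: float = 0.0
    lattice: str = "square"

    def __post_init__(self) -> None:
        if self.lattice not in ("square", "none"):
            raise GeometryError(f"unknown lattice {self.lattice!r}")
        if self.lattice == "square":
            if self.hole_diameter <= 0:
                raise GeometryError("hole_diameter must be positive for a square lattice")
            if self.hole_spacing < 0:
                raise GeometryError("hole_spacing must be non-negative (holes overlap)")

    @classmethod
    def continuous(cls) -> "HoleyFilmPattern":
        return cls(lattice="none")

    @property
    def is_continuous(self) -> bool:
        return self.lattice == "none"

    @property
    def pitch(self) -> float:
        """Lattice period d + s in µm."""
        if self.is_continuous:
            raise GeometryError("continuous film has no pitch")
        return self.hole_diameter + self.hole_spacing

    @property
    def name(self) -> str:
        if self.is_continuous:
            return "continuous"
        return f"{self.hole_diameter:g}/{self.hole_spacing:g}"


@dataclass(frozen=True)
class FilmMaterial:
    """Support-film material with its lumped thermal/optical parameter.

    ``alpha_eff`` (units K·µm⁻²·(W/cm²)⁻¹) lumps the film's absorptivity A
    over its conductance c; it is the single free thermal parameter of the
    heat model and is obtained by calibration, never from handbooks, because
    A and c are not separately identifiable from threshold measurements.
    For materials whose damage threshold could not be reached experimentally
    only an upper bound on alpha_eff is known (``alpha_upper_bound``).
    """

    name: str
    alpha_eff: Optional[float] = None
    alpha_upper_bound: Optional[float] = None
    autofluorescent: bool = False

    def __post_init__(self) -> None:
        if self.alpha_eff is not None and self.alpha_eff <= 0:
            raise GeometryError("alpha_eff must be positive when known")


@dataclass(frozen=True)
class GridSpec:
    """Full description of one support grid."""

    grid_id: str
    film_material: str
    film_pattern: HoleyFilmPattern
    mesh: Optional[int] = None
    square_size_L: Optional[float] = None  # µm
    bar_metal: str = "copper"
    film_thickness_nm: Optional[float] = None  # informational only
    supplier_name: str = ""
    extras: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.square_size_L is None and self.mesh is None:
            raise GeometryError("either mesh or square_size_L must be given")
        if self.square_size_L is None:
            object.__setattr__(self, "square_size_L", square_size_from_mesh(self.mesh))
        if self.square_size_L <= 0:
            raise GeometryError("square_size_L must be positive")
        if self.mesh is not None and self.square_size_L >= MICRONS_PER_INCH / self.mesh:
            raise GeometryError(
                f"square size {self.square_size_L} µm exceeds the {self.mesh}-mesh pitch "
                f"{MICRONS_PER_INCH / self.mesh:.1f} µm"
            )

    @property
    def eta_c(self) -> float:
        return carbon_area_fraction(self.film_pattern)


def carbon_area_fraction(pattern: HoleyFilmPattern) -> float:
    """Area fraction η_c of the film plane covered by material.

    For a square lattice of circular holes with diameter d and pitch d + s,

        η_c = 1 − π (d/2)² / (d + s)²,

    i.e. one hole per unit cell.  A continuous film has η_c = 1.  The
    standard patterns give 2/1 → 0.6509 (65 %), 1/4 → 0.9686 (97 %) and
    1.2/1.3 → 0.8190 (82 %).
    """
    if pattern.is_continuous:
        return 1.0
    d = pattern.hole_diameter
    pitch = pattern.pitch
    if d > pitch:
        raise GeometryError("holes overlap: diameter exceeds lattice pitch")
    frac = 1.0 - math.pi * (d / 2.0) ** 2 / pitch**2
    if frac <= 0.0:
        raise GeometryError("hole pattern leaves no film material")
    return frac


def square_size_from_mesh(mesh: int, bar_width: Optional[float] = None) -> float:
    """Grid-square size L (µm) for a given mesh (squares per inch).

    The standard meshes use the catalogued square sizes (90/58/37 µm for
    200/300/400); other meshes fall back to inch pitch minus bar width.
    """
    if mesh is None or mesh <= 0:
        raise GeometryError("mesh must be a positive count per inch")
    if bar_width is None and mesh in MESH_SQUARE_SIZE_UM:
        return MESH_SQUARE_SIZE_UM[mesh]
    bw = DEFAULT_BAR_WIDTH_UM if bar_width is None else bar_width
    size = MICRONS_PER_INCH / mesh - bw
    if size <= 0:
        raise GeometryError(
            f"mesh {mesh} with bar width {bw} µm leaves no open square ({size:.1f} µm)"
        )
    return size


def film_mask_at(pattern: HoleyFilmPattern, x: np.ndarray, y: np.ndarray, L: float) -> np.ndarray:
    """Evaluate the film-presence indicator at arbitrary coordinates (µm).

    The hole lattice is phase-centred on the grid square: a hole centre sits
    at (L/2, L/2) and the others follow on the square lattice of period
    ``pattern.pitch``.  Returns 1.0 where film is present, 0.0 inside holes.
    """
    if pattern.is_continuous:
        return np.ones(np.broadcast(x, y).shape)
    pitch = pattern.pitch
    # distance to the nearest lattice point, via wrap into [-pitch/2, pitch/2)
    dx = np.mod(np.asarray(x) - L / 2.0 + pitch / 2.0, pitch) - pitch / 2.0
    dy = np.mod(np.asarray(y) - L / 2.0 + pitch / 2.0, pitch) - pitch / 2.0
    r2 = dx * dx + dy * dy
    return np.where(r2 < (pattern.hole_diameter / 2.0) ** 2, 0.0, 1.0)


def film_mask(pattern: HoleyFilmPattern, L: float, resolution: float) -> np.ndarray:
    """Rasterize the film over one L×L grid square (1 = film, 0 = hole).

    ``resolution`` is in pixels per µm and must place at least 32 pixels
    across the square.  Pixels are sampled at their centres, origin at the
    square corner; the mask mean converges to ``carbon_area_fraction`` with
    error O(1/resolution).
    """
    carbon_area_fraction(pattern)  # validate geometry up front
    n = int(round(L * resolution))
    if n < 32:
        raise GeometryError(f"resolution gives only {n} pixels across the square (need ≥ 32)")
    centers = (np.arange(n) + 0.5) / resolution
    xx, yy = np.meshgrid(centers, centers)
    return film_mask_at(pattern, xx, yy, L)
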