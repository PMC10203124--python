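"""Steady-state and transient heat transport over one grid square.

Model
-----
Light absorbed by the support film heats the sample; the metal grid bars,
clamped to the liquid-nitrogen-cooled stage, hold the square's perimeter at
T₀ (Dirichlet boundary).  Convective cooling by the cold gas is negligible
against conduction and is not modelled.  With P the illumination power
density (W/cm²) and α the lumped film parameter (absorptivity over
conductance, K·µm⁻²·(W/cm²)⁻¹), the steady 1D balance along a line through
the square centre is

    d²T/dx² = −P·α,     T(0) = T(L) = T₀,

whose solution is the parabola

    T(x) = T₀ + (P·α/2)·x·(L − x),

peaking at the centre with T_peak = T₀ + P·α·L²/8.  The 2D generalisation
solves ∇²T = −α·q(x, y) on the square with q the local absorbed power
density (beam intensity × film mask), discretised with the standard 5-point
stencil and a direct sparse solve.

The model is deliberately qualitative: α is the only free parameter and is
obtained by calibration against measured damage thresholds, never from
material handbooks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ParameterError, SolverError
from .geometry import HoleyFilmPattern, film_mask_at
from .illumination import BeamProfile, intensity_at

__all__ = [
    "ThermalParams",
    "TemperatureField",
    "steady_1d",
    "peak_temperature",
    "steady_2d",
    "transient_2d",
    "node_source",
]

#: Liquid-nitrogen stage temperature (K).
DEFAULT_T0 = 77.0
#: Devitrification threshold of amorphous ice (K).
DEFAULT_TMAX = 136.0


@dataclass(frozen=True)
class ThermalParams:
    """Base temperature, devitrification threshold and film parameter."""

    T0: float = DEFAULT_T0
    Tmax: float = DEFAULT_TMAX
    alpha_eff: Optional[float] = None  # K·µm⁻²·(W/cm²)⁻¹

    def __post_init__(self) -> None:
        if not (self.Tmax > self.T0 > 0):
            raise ParameterError("require Tmax > T0 > 0")
        if self.alpha_eff is not None and self.alpha_eff <= 0:
            raise ParameterError("alpha_eff must be positive")


@dataclass(frozen=True)
class TemperatureField:
    """Temperature over one grid square: a 1D profile or a 2D raster.

    ``values`` holds node temperatures (K); ``x`` (and ``y`` for 2D) are the
    node coordinates in µm, spanning [0, L] inclusive so the first and last
    entries are the boundary nodes at T0.
    """

    values: np.ndarray
    x: np.ndarray
    T0: float
    y: Optional[np.ndarray] = None

    @property
    def dimensionality(self) -> int:
        return 1 if self.y is None else 2

    @property
    def peak_T(self) -> float:
        return float(np.max(self.values))

    @property
    def rise(self) -> float:
        """Peak temperature rise above the boundary (K)."""
        return self.peak_T - self.T0


def steady_1d(
    P: float,
    alpha_eff: float,
    L: float,
    T0: float = DEFAULT_T0,
    n_points: int = 257,
) -> TemperatureField:
    """Closed-form steady 1D profile T(x) = T0 + (Pα/2)·x·(L − x)."""
    if P < 0:
        raise ParameterError("illumination power density must be non-negative")
    if L <= 0 or alpha_eff <= 0:
        raise ParameterError("require L > 0 and alpha_eff > 0")
    x = np.linspace(0.0, L, n_points)
    values = T0 + 0.5 * P * alpha_eff * x * (L - x)
    return TemperatureField(values=values, x=x, T0=T0)


def peak_temperature(P: float, alpha_eff: float, L: float, T0: float = DEFAULT_T0) -> float:
    """Centre temperature T0 + P·α·L²/8 — linear in P, quadratic in L."""
    if P < 0:
        raise ParameterError("illumination power density must be non-negative")
    return T0 + P * alpha_eff * L**2 / 8.0


def _interior_laplacian(nx: int, ny: int, hx: float, hy: float) -> sp.csr_matrix:
    """5-point Laplacian on the (nx−2)×(ny−2) interior nodes, Dirichlet rows
    eliminated (row-major / y-outer node ordering)."""
    mx, my = nx - 2, ny - 2
    ex = np.ones(mx)
    ey = np.ones(my)
    d2x = sp.diags([ex[:-1], -2.0 * ex, ex[:-1]], [-1, 0, 1]) / hx**2
    d2y = sp.diags([ey[:-1], -2.0 * ey, ey[:-1]], [-1, 0, 1]) / hy**2
    return (sp.kron(sp.identity(my), d2x) + sp.kron(d2y, sp.identity(mx))).tocsr()


def node_source(
    pattern: HoleyFilmPattern,
    beam: BeamProfile | float,
    L: float,
    resolution: float,
    Ly: Optional[float] = None,
    supersample: int = 4,
) -> np.ndarray:
    """Absorbed-power raster q(x, y) (W/cm²) sampled at solver nodes.

    q = local beam intensity × film-presence mask, evaluated on the
    (ny, nx) node grid spanning [0, L]×[0, Ly] inclusive.  ``beam`` may be a
    plain number, shorthand for a uniform beam of that power density.
    ``supersample`` > 1 antialiases the hole mask by averaging an s×s
    sub-grid within each node cell, which sharply reduces the area bias of
    a binary mask at moderate resolutions; 1 gives the raw binary mask.
    """
    Ly = L if Ly is None else Ly
    nx = int(round(L * resolution)) + 1
    ny = int(round(Ly * resolution)) + 1
    x = np.linspace(0.0, L, nx)
    y = np.linspace(0.0, Ly, ny)
    xx, yy = np.meshgrid(x, y)
    if supersample < 1:
        raise ParameterError("supersample must be a positive integer")
    if supersample == 1:
        mask = film_mask_at(pattern, xx, yy, L)
    else:
        h = 1.0 / resolution
        offsets = ((np.arange(supersample) + 0.5) / supersample - 0.5) * h
        mask = np.zeros_like(xx)
        for ox in offsets:
            for oy in offsets:
                mask += film_mask_at(pattern, xx + ox, yy + oy, L)
        mask /= supersample**2
    if isinstance(beam, BeamProfile):
        if beam.kind == "uniform":
            inten = np.full_like(mask, beam.peak_density_P)
        else:
            r = np.sqrt(
                (xx - (L / 2.0 + beam.center_offset[0])) ** 2
                + (yy - (Ly / 2.0 + beam.center_offset[1])) ** 2
            )
            inten = intensity_at(beam, r)
    else:
        inten = np.full_like(mask, float(beam))
    return inten * mask


def steady_2d(
    source: np.ndarray,
    alpha_eff: float,
    Lx: float,
    Ly: float,
    T0: float = DEFAULT_T0,
    residual_tol: float = 1e-10,
) -> TemperatureField:
    """Solve ∇²T = −α·q with T = T0 on all four edges.

    ``source`` is the absorbed-power raster q (W/cm²) on the (ny, nx) node
    grid spanning the square inclusive of boundaries (boundary values are
    ignored — the Dirichlet condition wins there).  Discretisation is the
    5-point stencil on interior nodes with a direct sparse solve; the
    relative residual of the discrete system is verified < ``residual_tol``,
    with an iterative fallback before failing.
    """
    source = np.asarray(source, dtype=float)
    if source.ndim != 2:
        raise ParameterError("source raster must be 2D")
    ny, nx = source.shape
    if nx < 33 or ny < 33:
        raise ParameterError(
            f"raster {ny}×{nx} too coarse: need ≥ 32 intervals across each side"
        )
    if Lx <= 0 or Ly <= 0 or alpha_eff <= 0:
        raise ParameterError("require Lx, Ly, alpha_eff > 0")
    if np.any(source < 0):
        raise ParameterError("absorbed power must be non-negative")
    hx = Lx / (nx - 1)
    hy = Ly / (ny - 1)
    lap = _interior_laplacian(nx, ny, hx, hy)
    rhs = alpha_eff * source[1:-1, 1:-1].ravel()
    A = (-lap).tocsc()
    theta = spla.spsolve(A, rhs)
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm > 0:
        res = np.linalg.norm(A @ theta - rhs) / rhs_norm
        if res > residual_tol:
            theta, info = spla.cg(A, rhs, x0=theta, rtol=residual_tol / 10)
            res = np.linalg.norm(A @ theta - rhs) / rhs_norm
            if info != 0 or res > residual_tol:
                raise SolverError(
                    f"discrete residual {res:.2e} exceeds {residual_tol:.0e} "
                    f"(grid {ny}×{nx}, cg info {info})"
                )
    values = np.full((ny, nx), T0)
    values[1:-1, 1:-1] += theta.reshape(ny - 2, nx - 2)
    return TemperatureField(
        values=values,
        x=np.linspace(0.0, Lx, nx),
        y=np.linspace(0.0, Ly, ny),
        T0=T0,
    )


def transient_2d(
    source: np.ndarray,
    alpha_eff: float,
    heat_capacity_scale: float,
    dt: float,
    t_end: float,
    Lx: float,
    Ly: float,
    T0: float = DEFAULT_T0,
    T_init: Optional[np.ndarray] = None,
    scheme: str = "implicit",
    store_every: int = 1,
) -> List[TemperatureField]:
    """Time-march κ·∂T/∂t = ∇²T + α·q toward the steady state.

    ``heat_capacity_scale`` κ (s·µm²·µm⁻², i.e. an inverse diffusivity) sets
    how fast the field equilibrates; it is a demonstration parameter only —
    the steady state it converges to is independent of κ.  The implicit
    (backward-Euler) scheme is unconditionally stable and is the default;
    the explicit scheme enforces dt ≤ κ / (2·(1/hx² + 1/hy²)) and raises
    naming that bound otherwise.  Returns the stored fields in time order,
    always including the final time.
    """
    source = np.asarray(source, dtype=float)
    ny, nx = source.shape
    if heat_capacity_scale <= 0 or dt <= 0 or t_end <= 0:
        raise ParameterError("require heat_capacity_scale, dt, t_end > 0")
    hx = Lx / (nx - 1)
    hy = Ly / (ny - 1)
    lap = _interior_laplacian(nx, ny, hx, hy)
    m = (nx - 2) * (ny - 2)
    q = alpha_eff * source[1:-1, 1:-1].ravel()
    kappa = heat_capacity_scale
    if scheme == "explicit":
        dt_max = kappa / (2.0 * (1.0 / hx**2 + 1.0 / hy**2))
        if dt > dt_max:
            raise ParameterError(
                f"explicit scheme unstable at dt = {dt:g}; stable bound is "
                f"dt ≤ κ/(2(1/hx²+1/hy²)) = {dt_max:g}"
            )
        step_mat = None
    elif scheme == "implicit":
        step_mat = spla.splu((sp.identity(m) - (dt / kappa) * lap).tocsc())
    else:
        raise ParameterError(f"unknown scheme {scheme!r}")

    if T_init is None:
        theta = np.zeros(m)
    else:
        T_init = np.asarray(T_init, dtype=float)
        if T_init.shape != source.shape:
            raise ParameterError("T_init shape must match the source raster")
        theta = (T_init[1:-1, 1:-1] - T0).ravel()

    def snapshot(th: np.ndarray) -> TemperatureField:
        vals = np.full((ny, nx), T0)
        vals[1:-1, 1:-1] += th.reshape(ny - 2, nx - 2)
        return TemperatureField(
            values=vals, x=np.linspace(0, Lx, nx), y=np.linspace(0, Ly, ny), T0=T0
        )

    n_steps = max(1, int(round(t_end / dt)))
    fields: List[TemperatureField] = []
    for k in range(1, n_steps + 1):
        if scheme == "explicit":
            theta = theta + (dt / kappa) * (lap @ theta + q)
        else:
            theta = step_mat.solve(theta + (dt / kappa) * q)
        if k % store_every == 0 or k == n_steps:
            fields.append(snapshot(theta))
    return fields
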