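"""Calibration of film parameters and grid-selection analyses.

The heat model leaves a single free parameter per film material: the lumped
α = A/c (absorptivity over conductance).  Inverting the uniform-illumination
threshold relation

    P_max = 8·(T_max − T₀) / (α · η_c · L²)

turns each measured threshold into an α sample; the per-material estimate
minimises squared log-residuals (thresholds span more than a 40-fold range,
so the error model is multiplicative), which makes α̂ the geometric mean of
the per-row inversions.  Censored measurements — thresholds the instrument
could not reach ("> 690 W/cm²") or only bounded from above ("< 50 W/cm²") —
never enter the point fit; they yield one-sided bounds on α and are checked
for consistency against the fitted prediction.

The same closed form drives the scaling-law check (η_c·P_max = C for films
differing only in hole pattern), threshold prediction for new grids (bar
metal does not enter: the bars are ideal isothermal sinks), and grid
ranking under the 70 % operating rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .damage import SAFETY_FACTOR, max_power_density
from .errors import CensoredValue, MissingDataError, ParameterError
from .geometry import GridSpec, HoleyFilmPattern, carbon_area_fraction
from .heat import ThermalParams

__all__ = [
    "ThresholdMeasurement",
    "MaterialFit",
    "CalibrationResult",
    "fit_alpha",
    "scaling_law_check",
    "comparison_report",
    "predict_threshold",
    "rank_grids",
]

_CENSOR_FROM_CSV = {"none": "none", "gt": "lower_bound", "lt": "upper_bound"}


@dataclass(frozen=True)
class ThresholdMeasurement:
    """A measured (or simulated) maximum illumination power density."""

    grid_id: str
    measured_Pmax: float  # W/cm²
    censor: str = "none"  # none | lower_bound ("> value") | upper_bound ("< value")

    def __post_init__(self) -> None:
        if self.measured_Pmax <= 0:
            raise ParameterError("measured_Pmax must be positive")
        if self.censor not in ("none", "lower_bound", "upper_bound"):
            raise ParameterError(f"unknown censor kind {self.censor!r}")


@dataclass
class MaterialFit:
    """Per-material calibration outcome."""

    material: str
    alpha: Optional[float] = None  # point estimate (K·µm⁻²·(W/cm²)⁻¹)
    alpha_upper_bound: Optional[float] = None  # from "> P" rows
    alpha_lower_bound: Optional[float] = None  # from "< P" rows
    n_uncensored: int = 0
    log_residuals: Dict[str, float] = field(default_factory=dict)
    censored_consistent: Dict[str, bool] = field(default_factory=dict)


@dataclass
class CalibrationResult:
    materials: Dict[str, MaterialFit]
    thermal: ThermalParams

    def alpha_for(self, material: str) -> Union[float, CensoredValue]:
        if material not in self.materials:
            raise MissingDataError(
                f"material {material!r} not calibrated; available: "
                f"{sorted(self.materials)}"
            )
        fit = self.materials[material]
        if fit.alpha is not None:
            return fit.alpha
        if fit.alpha_upper_bound is not None:
            return CensoredValue(fit.alpha_upper_bound, "upper")
        if fit.alpha_lower_bound is not None:
            return CensoredValue(fit.alpha_lower_bound, "lower")
        raise MissingDataError(f"material {material!r} has no usable calibration")


def _row_geometry(row: pd.Series) -> Tuple[float, float]:
    """(η_c, L) for a catalogue row."""
    d = row.get("hole_diameter_um")
    s = row.get("hole_spacing_um")
    if d is None or (isinstance(d, float) and math.isnan(d)):
        pattern = HoleyFilmPattern.continuous()
    else:
        pattern = HoleyFilmPattern(float(d), float(s))
    return carbon_area_fraction(pattern), float(row["square_size_um"])


def _alpha_from_row(P: float, eta: float, L: float, thermal: ThermalParams) -> float:
    return 8.0 * (thermal.Tmax - thermal.T0) / (eta * P * L**2)


def fit_alpha(catalogue: pd.DataFrame, thermal: ThermalParams) -> CalibrationResult:
    """Fit per-material α from a catalogue of threshold measurements.

    The catalogue is a DataFrame in the standard dialect (see
    :func:`gridheat.io.load_catalogue`); rows repeating a grid_id (the same
    physical grid listed under several comparisons) are de-duplicated before
    fitting.  Uncensored rows of a material give α̂ as the geometric mean of
    the closed-form inversions; censored rows contribute bounds on α and a
    consistency flag (is the bound satisfied by the fitted prediction?).
    """
    df = catalogue.drop_duplicates(subset="grid_id")
    result = CalibrationResult(materials={}, thermal=thermal)
    for material, grp in df.groupby("film_material", sort=True):
        fit = MaterialFit(material=material)
        alphas: List[Tuple[str, float, float, float, float]] = []
        for _, row in grp.iterrows():
            eta, L = _row_geometry(row)
            P = float(row["measured_pmax_W_cm2"])
            censor = _CENSOR_FROM_CSV.get(str(row.get("censor", "none")), str(row.get("censor")))
            a = _alpha_from_row(P, eta, L, thermal)
            if censor == "none":
                alphas.append((row["grid_id"], a, eta, L, P))
            elif censor == "lower_bound":
                # threshold exceeds P ⇒ α below the inversion at P
                fit.alpha_upper_bound = (
                    a if fit.alpha_upper_bound is None else min(fit.alpha_upper_bound, a)
                )
            elif censor == "upper_bound":
                fit.alpha_lower_bound = (
                    a if fit.alpha_lower_bound is None else max(fit.alpha_lower_bound, a)
                )
            else:
                raise ParameterError(f"unknown censor value {censor!r}")
        fit.n_uncensored = len(alphas)
        if alphas:
            fit.alpha = float(np.exp(np.mean([math.log(a) for _, a, *_ in alphas])))
            for grid_id, _, eta, L, P in alphas:
                pred = max_power_density(fit.alpha, L, thermal.T0, thermal.Tmax, eta)
                fit.log_residuals[grid_id] = math.log(P) - math.log(pred)
            # consistency of censored rows against the fitted material
            for _, row in grp.iterrows():
                censor = _CENSOR_FROM_CSV.get(str(row.get("censor", "none")))
                if censor in ("lower_bound", "upper_bound"):
                    eta, L = _row_geometry(row)
                    P = float(row["measured_pmax_W_cm2"])
                    pred = max_power_density(fit.alpha, L, thermal.T0, thermal.Tmax, eta)
                    ok = pred >= P if censor == "lower_bound" else pred <= P
                    fit.censored_consistent[row["grid_id"]] = bool(ok)
        result.materials[material] = fit
    return result


def scaling_law_check(
    pair1: Tuple[float, float], pair2: Tuple[float, float]
) -> float:
    """Relative difference (%) of η_c·P_max between two film geometries.

    For films differing only in hole pattern the model predicts
    η_c·P_max = C constant; the check returns
    100·|η₁P₁ − η₂P₂| / max(η₁P₁, η₂P₂), symmetric in its arguments.
    Censored thresholds are rejected.
    """
    for eta, P in (pair1, pair2):
        if isinstance(P, CensoredValue):
            raise ParameterError("scaling-law check requires uncensored thresholds")
        if not 0.0 < eta <= 1.0 or P <= 0:
            raise ParameterError("require 0 < η_c ≤ 1 and P_max > 0")
    c1 = pair1[0] * pair1[1]
    c2 = pair2[0] * pair2[1]
    return 100.0 * abs(c1 - c2) / max(c1, c2)


def _find_row(
    df: pd.DataFrame,
    material: str,
    pattern: Optional[str],
    mesh: int,
    bar_metal: Optional[str] = None,
    label: str = "",
) -> pd.Series:
    sel = (df["film_material"] == material) & (df["mesh"].astype(int) == mesh)
    if pattern is not None:
        d, s = (float(v) for v in pattern.split("/"))
        sel &= (df["hole_diameter_um"].astype(float) == d) & (
            df["hole_spacing_um"].astype(float) == s
        )
    if bar_metal is not None:
        sel &= df["bar_metal"] == bar_metal
    hits = df[sel]
    if hits.empty:
        raise MissingDataError(
            f"catalogue row not found: {label or f'{material} {pattern} {mesh}-mesh {bar_metal}'}"
        )
    return hits.iloc[0]


def comparison_report(catalogue: pd.DataFrame) -> dict:
    """The grid-selection comparisons, computed from a measurement catalogue.

    Returns a dict with four sections: the mesh series (measured threshold
    ratios against the model's 1/L² prediction, reported as a
    model-adequacy deviation — the model is explicitly qualitative), the
    copper/gold bar-metal equality check, the manufacturing ratio
    (Quantifoil vs CFlat at identical geometry), and the η_c·P_max
    scaling-law checks for both film-geometry pairs.
    """
    df = catalogue.drop_duplicates(subset="grid_id")

    # (a) mesh series: CFlat 2/1 on 200/300/400 mesh
    series = []
    for mesh in (200, 300, 400):
        row = _find_row(df, "carbon_cflat", "2/1", mesh, label=f"CFlat 2/1 {mesh}-mesh")
        eta, L = _row_geometry(row)
        series.append(
            {"mesh": mesh, "L_um": L, "measured_pmax_W_cm2": float(row["measured_pmax_W_cm2"])}
        )
    mesh_pairs = []
    for lo, hi in zip(series, series[1:]):
        measured_ratio = hi["measured_pmax_W_cm2"] / lo["measured_pmax_W_cm2"]
        model_ratio = (lo["L_um"] / hi["L_um"]) ** 2
        mesh_pairs.append(
            {
                "meshes": (lo["mesh"], hi["mesh"]),
                "measured_ratio": measured_ratio,
                "model_ratio_L2": model_ratio,
                "deviation_pct": 100.0 * (model_ratio - measured_ratio) / model_ratio,
            }
        )

    # (b) bar-metal pair: identical CFlat 1.2/1.3 300-mesh film on Cu vs Au
    cu = _find_row(df, "carbon_cflat", "1.2/1.3", 300, "copper", "CFlat 1.2/1.3 300-mesh Cu")
    au = _find_row(df, "carbon_cflat", "1.2/1.3", 300, "gold", "CFlat 1.2/1.3 300-mesh Au")
    metal = {
        "copper_pmax": float(cu["measured_pmax_W_cm2"]),
        "gold_pmax": float(au["measured_pmax_W_cm2"]),
        "ratio": float(cu["measured_pmax_W_cm2"]) / float(au["measured_pmax_W_cm2"]),
    }

    # (c) manufacturing: Quantifoil vs CFlat, identical 2/1 200-mesh copper
    qf = _find_row(df, "carbon_quantifoil", "2/1", 200, label="Quantifoil 2/1 200-mesh")
    cf = _find_row(df, "carbon_cflat", "2/1", 200, label="CFlat 2/1 200-mesh")
    manu_pct = 100.0 * float(qf["measured_pmax_W_cm2"]) / float(cf["measured_pmax_W_cm2"])
    manufacturing = {
        "quantifoil_pmax": float(qf["measured_pmax_W_cm2"]),
        "cflat_pmax": float(cf["measured_pmax_W_cm2"]),
        "ratio_pct": manu_pct,
        "ratio_pct_rounded": round(manu_pct),
    }

    # (d) scaling law for both film-geometry pairs
    def _pair(material: str, p1: str, p2: str, mesh: int) -> dict:
        rows = [_find_row(df, material, p, mesh, label=f"{material} {p} {mesh}") for p in (p1, p2)]
        pairs = [
            (_row_geometry(r)[0], float(r["measured_pmax_W_cm2"])) for r in rows
        ]
        return {
            "material": material,
            "patterns": (p1, p2),
            "eta_pmax_products": [eta * P for eta, P in pairs],
            "relative_difference_pct": scaling_law_check(*pairs),
        }

    film_geometry = [
        _pair("carbon_cflat", "2/1", "1.2/1.3", 300),
        _pair("carbon_quantifoil", "2/1", "1/4", 200),
    ]

    return {
        "mesh_series": {"series": series, "pairs": mesh_pairs},
        "bar_metal": metal,
        "manufacturing": manufacturing,
        "film_geometry": film_geometry,
    }


def predict_threshold(
    spec: GridSpec, calibration: CalibrationResult, thermal: Optional[ThermalParams] = None
) -> Union[float, CensoredValue]:
    """Predicted P_max (W/cm²) for a grid, from a calibrated material.

    Bar metal and film thickness deliberately do not enter: the bars are
    ideal isothermal sinks and thickness is absorbed into α.  Materials
    known only through censored measurements propagate to bound-only
    predictions (an upper bound on α gives a lower bound on P_max).
    """
    thermal = thermal or calibration.thermal
    alpha = calibration.alpha_for(spec.film_material)
    eta = spec.eta_c
    L = spec.square_size_L
    if isinstance(alpha, CensoredValue):
        p = max_power_density(alpha.bound, L, thermal.T0, thermal.Tmax, eta)
        # α bounded above ⇒ threshold bounded below, and vice versa
        return CensoredValue(p, "lower" if alpha.kind == "upper" else "upper")
    return max_power_density(alpha, L, thermal.T0, thermal.Tmax, eta)


def rank_grids(
    specs: List[GridSpec],
    calibration: CalibrationResult,
    required_P: float,
    thermal: Optional[ThermalParams] = None,
) -> pd.DataFrame:
    """Rank grid designs by predicted threshold under the 70 % rule.

    Descending by predicted P_max (bound value for censored predictions);
    ties broken by lower η_c, then smaller L, then grid_id, so the order is
    deterministic.  A design is usable when required_P ≤ 0.70 × predicted;
    for upper-bound predictions usability cannot be guaranteed and is False
    unless even the bound suffices — conservatively never, since the true
    threshold may lie anywhere below it.
    """
    if required_P < 0:
        raise ParameterError("required power must be non-negative")
    rows = []
    for spec in specs:
        pred = predict_threshold(spec, calibration, thermal)
        if isinstance(pred, CensoredValue):
            value, kind = pred.bound, pred.kind
            usable = kind == "lower" and required_P <= SAFETY_FACTOR * value
        else:
            value, kind = pred, "none"
            usable = required_P <= SAFETY_FACTOR * value
        rows.append(
            {
                "grid_id": spec.grid_id,
                "film_material": spec.film_material,
                "pattern": spec.film_pattern.name,
                "mesh": spec.mesh,
                "square_size_um": spec.square_size_L,
                "eta_c": spec.eta_c,
                "predicted_pmax_W_cm2": value,
                "prediction_bound": kind,
                "recommended_P_W_cm2": SAFETY_FACTOR * value,
                "usable": usable,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        by=["predicted_pmax_W_cm2", "eta_c", "square_size_um", "grid_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
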