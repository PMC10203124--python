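"""Reading and writing the package's standard formats.

The catalogue CSV dialect (one row per threshold measurement) is shared by
the packaged measurement table, synthetic datasets and user catalogues, so
real and simulated data are interchangeable everywhere.  Temperature fields
export as CSV matrices or 32-bit float TIFF rasters with a JSON metadata
sidecar; calibrations round-trip through JSON; beams load from YAML/JSON
config files.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .calibrate import CalibrationResult, MaterialFit
from .geometry import GridSpec, HoleyFilmPattern
from .heat import TemperatureField, ThermalParams
from .illumination import BeamProfile

__all__ = [
    "load_catalogue",
    "spec_from_row",
    "catalogue_specs",
    "save_calibration",
    "load_calibration",
    "field_to_csv",
    "field_to_tiff",
    "load_beam_config",
]

_CATALOGUE_COLUMNS = [
    "grid_id",
    "supplier_name",
    "film_material",
    "hole_diameter_um",
    "hole_spacing_um",
    "mesh",
    "square_size_um",
    "bar_metal",
    "measured_pmax_W_cm2",
    "censor",
]


def load_catalogue(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Load a grid catalogue CSV; default is the packaged measurement table."""
    if path is None:
        with resources.files("gridheat.data").joinpath("table1.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = set(_CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    return df


def spec_from_row(row: pd.Series) -> GridSpec:
    """Build a GridSpec from one catalogue row."""
    d = row.get("hole_diameter_um")
    if d is None or (isinstance(d, float) and math.isnan(d)):
        pattern = HoleyFilmPattern.continuous()
    else:
        pattern = HoleyFilmPattern(float(d), float(row["hole_spacing_um"]))
    mesh = row.get("mesh")
    return GridSpec(
        grid_id=str(row["grid_id"]),
        film_material=str(row["film_material"]),
        film_pattern=pattern,
        mesh=None if pd.isna(mesh) else int(mesh),
        square_size_L=float(row["square_size_um"]),
        bar_metal=str(row.get("bar_metal", "copper")),
        supplier_name=str(row.get("supplier_name", "")),
    )


def catalogue_specs(df: pd.DataFrame) -> List[GridSpec]:
    """Unique GridSpecs from a catalogue (duplicated grid_ids collapsed)."""
    return [spec_from_row(row) for _, row in df.drop_duplicates(subset="grid_id").iterrows()]


def save_calibration(calibration: CalibrationResult, path: Union[str, Path]) -> None:
    payload = {
        "thermal": {
            "T0": calibration.thermal.T0,
            "Tmax": calibration.thermal.Tmax,
        },
        "materials": {
            m: {
                "alpha": fit.alpha,
                "alpha_upper_bound": fit.alpha_upper_bound,
                "alpha_lower_bound": fit.alpha_lower_bound,
                "n_uncensored": fit.n_uncensored,
                "log_residuals": fit.log_residuals,
                "censored_consistent": fit.censored_consistent,
            }
            for m, fit in calibration.materials.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path: Union[str, Path]) -> CalibrationResult:
    payload = json.loads(Path(path).read_text())
    thermal = ThermalParams(T0=payload["thermal"]["T0"], Tmax=payload["thermal"]["Tmax"])
    materials = {
        m: MaterialFit(
            material=m,
            alpha=d["alpha"],
            alpha_upper_bound=d["alpha_upper_bound"],
            alpha_lower_bound=d["alpha_lower_bound"],
            n_uncensored=d["n_uncensored"],
            log_residuals=d["log_residuals"],
            censored_consistent=d["censored_consistent"],
        )
        for m, d in payload["materials"].items()
    }
    return CalibrationResult(materials=materials, thermal=thermal)


def field_to_csv(field: TemperatureField, path: Union[str, Path]) -> None:
    """Write a temperature field as a CSV matrix (1D: x,T columns)."""
    if field.dimensionality == 1:
        pd.DataFrame({"x_um": field.x, "T_K": field.values}).to_csv(path, index=False)
    else:
        np.savetxt(path, field.values, delimiter=",")


def field_to_tiff(
    field: TemperatureField, path: Union[str, Path], extra_metadata: Optional[dict] = None
) -> None:
    """Write a 2D field as 32-bit float TIFF with a JSON metadata sidecar."""
    import tifffile

    if field.dimensionality != 2:
        raise ValueError("TIFF export requires a 2D field")
    path = Path(path)
    tifffile.imwrite(path, field.values.astype(np.float32))
    meta = {
        "Lx_um": float(field.x[-1] - field.x[0]),
        "Ly_um": float(field.y[-1] - field.y[0]),
        "nx": int(field.values.shape[1]),
        "ny": int(field.values.shape[0]),
        "T0_K": field.T0,
        "peak_T_K": field.peak_T,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_beam_config(path: Union[str, Path]) -> BeamProfile:
    """Load a beam description from a YAML or JSON config file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return BeamProfile.from_config(cfg)
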