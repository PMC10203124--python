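"""From temperature fields to devitrification predictions.

Damage to the vitrified sample sets in wherever the steady-state temperature
exceeds the devitrification threshold T_max (≈136 K).  Because the system is
in steady state, damage is governed by dose *rate* (instantaneous power
density), not cumulative dose; once a region has devitrified it does not
heal, so damage under a varying power schedule is the running maximum of the
instantaneous extent.

Post-illumination squares are classified into four ordinal states of
increasing severity: (1) no effect, (2) onset confined to the centre,
(3) pronounced central damage, (4) destruction over a large fraction of the
square.  The model maps states to the fraction of the square area above
T_max; the two boundary fractions are configurable because the experimental
states are visual categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import CensoredValue, ParameterError
from .heat import TemperatureField, steady_2d

__all__ = [
    "DamageAssessment",
    "OperatingRecommendation",
    "SAFETY_FACTOR",
    "max_power_density",
    "damage_half_width",
    "classify_state",
    "recommend_operating_power",
    "damage_front_progression",
]

#: Operating rule: run at 70 % of the measured/predicted damage threshold.
SAFETY_FACTOR = 0.70

#: Default state boundaries: fraction of square area above T_max.
F_ONSET = 0.05
F_SEVERE = 0.50


@dataclass(frozen=True)
class DamageAssessment:
    state: int  # 1..4
    fraction_above_Tmax: float
    affected_half_width: float  # µm: half-extent (1D) or equivalent radius (2D)
    peak_T: float


@dataclass(frozen=True)
class OperatingRecommendation:
    grid_id: str
    predicted_Pmax: float  # W/cm²
    recommended_P: float  # W/cm² (= SAFETY_FACTOR × predicted)


def max_power_density(
    alpha_eff: float,
    L: float,
    T0: float,
    Tmax: float,
    eta_c: float = 1.0,
    source_unit: Optional[np.ndarray] = None,
    Ly: Optional[float] = None,
) -> float:
    """Maximum illumination power density P_max (W/cm²) before devitrification.

    Uniform illumination admits the closed form

        P_max = 8·(Tmax − T0) / (α · η_c · L²),

    where the holey film's absorption is homogenised as material α scaled by
    the carbon fraction η_c.  Passing ``source_unit`` — the absorbed-power
    raster at unit peak power density, e.g. an explicit hole mask times a
    Gaussian beam — switches to the numerical route: the 2D steady solve is
    linear in P, so the peak rise at unit power determines the threshold.
    """
    if Tmax <= T0:
        raise ParameterError("require Tmax > T0")
    if alpha_eff is None or alpha_eff <= 0:
        raise ParameterError("alpha_eff must be positive (calibrate the material first)")
    if source_unit is None:
        if not 0.0 < eta_c <= 1.0:
            raise ParameterError("carbon fraction must lie in (0, 1]")
        return 8.0 * (Tmax - T0) / (alpha_eff * eta_c * L**2)
    field = steady_2d(source_unit, alpha_eff, L, L if Ly is None else Ly, T0=0.0)
    if field.peak_T <= 0:
        raise ParameterError("unit source produces no heating; threshold is unbounded")
    return (Tmax - T0) / field.peak_T


def damage_half_width(P: float, P_threshold: float, L: float) -> float:
    """Half-width (µm) of the devitrified band around the square centre.

    The 1D steady profile is a parabola peaking at the centre; the region
    exceeding T_max at power P > P_threshold has half-width
    (L/2)·√(1 − P_threshold/P).  Zero at onset, → L/2 as P → ∞.
    """
    if P <= 0 or P_threshold <= 0 or L <= 0:
        raise ParameterError("require P, P_threshold, L > 0")
    if P <= P_threshold:
        return 0.0
    return (L / 2.0) * math.sqrt(1.0 - P_threshold / P)


def _affected_extent(field: TemperatureField, Tmax: float) -> Tuple[float, float]:
    """(area fraction above Tmax, affected half-width in µm)."""
    above = field.values > Tmax
    frac = float(np.mean(above))
    if field.dimensionality == 1:
        if not above.any():
            return frac, 0.0
        xs = field.x[above]
        return frac, float(xs.max() - xs.min()) / 2.0
    # 2D: equivalent radius of the affected area
    area = frac * (field.x[-1] - field.x[0]) * (field.y[-1] - field.y[0])
    return frac, math.sqrt(area / math.pi)


def classify_state(
    field: TemperatureField,
    Tmax: float,
    f_onset: float = F_ONSET,
    f_severe: float = F_SEVERE,
) -> DamageAssessment:
    """Four-state damage classification of a temperature field.

    State 1: nothing above T_max.  State 2: onset confined near the centre
    (area fraction ≤ f_onset).  State 3: pronounced central damage
    (≤ f_severe).  State 4: damage over a large fraction of the square.
    """
    if not 0.0 < f_onset < f_severe < 1.0:
        raise ParameterError("require 0 < f_onset < f_severe < 1")
    frac, half_width = _affected_extent(field, Tmax)
    if frac == 0.0:
        state = 1
    elif frac <= f_onset:
        state = 2
    elif frac <= f_severe:
        state = 3
    else:
        state = 4
    return DamageAssessment(
        state=state,
        fraction_above_Tmax=frac,
        affected_half_width=half_width,
        peak_T=field.peak_T,
    )


def recommend_operating_power(
    predicted_Pmax: float | CensoredValue, grid_id: str = ""
) -> OperatingRecommendation:
    """Apply the 70 % safety rule to a predicted threshold.

    A lower-bound threshold (material too weakly absorbing to damage within
    the instrument's range) is treated at its bound, which is conservative.
    """
    if isinstance(predicted_Pmax, CensoredValue):
        if not predicted_Pmax.is_lower:
            raise ParameterError(
                "cannot recommend an operating power from an upper-bound threshold"
            )
        predicted_Pmax = predicted_Pmax.bound
    if predicted_Pmax <= 0:
        raise ParameterError("predicted threshold must be positive")
    return OperatingRecommendation(
        grid_id=grid_id,
        predicted_Pmax=float(predicted_Pmax),
        recommended_P=SAFETY_FACTOR * float(predicted_Pmax),
    )


def damage_front_progression(
    power_schedule: Sequence[Tuple[float, float]],
    P_threshold: float,
    L: float,
) -> np.ndarray:
    """Damage half-width after each step of a (time, power) schedule.

    Heating equilibrates within tens of milliseconds, so each step's extent
    is the instantaneous steady-state half-width; devitrification is
    irreversible, so the profile over time is the running maximum.  Any
    schedule entirely below threshold yields zero damage regardless of
    duration — dose rate, not dose, governs damage.
    """
    times = [t for t, _ in power_schedule]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ParameterError("schedule times must be strictly increasing")
    widths = np.array([damage_half_width(P, P_threshold, L) for _, P in power_schedule])
    return np.maximum.accumulate(widths)
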