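"""Exception types and censored-value semantics shared across the package."""

from __future__ import annotations

from dataclasses import dataclass


class GridHeatError(Exception):
    """Base class for all package errors."""


class GeometryError(GridHeatError):
    """Invalid grid or film geometry (overlapping holes, non-positive square)."""


class ParameterError(GridHeatError):
    """Invalid physical or numerical parameter."""


class SolverError(GridHeatError):
    """Linear system could not be solved to the required residual."""


class MissingDataError(GridHeatError):
    """A required catalogue row or calibrated material is absent."""


@dataclass(frozen=True)
class CensoredValue:
    """A one-sided bound standing in for an unknown quantity.

    ``kind`` is ``"lower"`` when the true value is known to exceed ``bound``
    (e.g. a threshold the instrument could not reach) and ``"upper"`` when it
    is known to lie below it.  Arithmetic is deliberately not supported:
    callers must branch on censoring explicitly.
    """

    bound: float
    kind: str  # "lower" | "upper"

    def __post_init__(self) -> None:
        if self.kind not in ("lower", "upper"):
            raise ParameterError(f"censor kind must be 'lower' or 'upper', got {self.kind!r}")

    @property
    def is_lower(self) -> bool:
        return self.kind == "lower"

    def __float__(self) -> float:
        return float(self.bound)
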