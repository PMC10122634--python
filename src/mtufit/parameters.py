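"""Registry of the nine independent musculotendon parameters.

Each parameter has a default value and closed optimisation bounds.  The two
length parameters are expressed as dimensionless scaling factors applied to
the subject-scaled optimal fibre length and tendon slack length, so they are
comparable between subjects of different size.  Stiffness parameters
(``k_low_f``, ``k_one_f``, ``k_one_t``) are fully dependent on the strain
parameters and are never free; they are recomputed, never set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .curves import FibreCurveParams, TendonCurveParams

__all__ = [
    "PARAMETER_TABLE",
    "PARAMETER_NAMES",
    "DEFAULT_PARAMS",
    "ParameterBounds",
    "BoundsError",
    "validate_params",
    "fibre_params_from",
    "tendon_params_from",
    "read_param_file",
    "write_param_file",
]


class BoundsError(ValueError):
    """A parameter value falls outside its allowed interval."""


# name -> (default, lower, upper)
PARAMETER_TABLE: dict[str, tuple[float, float, float]] = {
    "lof_scale": (1.0, 0.5, 2.0),
    "eps_zero_f": (0.0, -0.5, 0.5),
    "eps_one_f": (0.70, 0.5, 1.5),
    "k_low_scale": (0.14, 0.01, 0.99),
    "curviness_f": (0.75, 0.0, 1.0),
    "lst_scale": (1.0, 0.5, 2.0),
    "eps_one_t": (0.049, 0.01, 5.0),
    "f_toe_t": (0.67, 0.01, 0.99),
    "curviness_t": (0.5, 0.0, 1.0),
}

PARAMETER_NAMES: tuple[str, ...] = tuple(PARAMETER_TABLE)

DEFAULT_PARAMS: dict[str, float] = {k: v[0] for k, v in PARAMETER_TABLE.items()}


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (default, lower, upper); lower <= default <= upper."""

    table: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(PARAMETER_TABLE)
    )

    def __post_init__(self) -> None:
        for name, (d, lo, hi) in self.table.items():
            if not lo <= d <= hi:
                raise BoundsError(
                    f"default of {name!r} ({d}) outside [{lo}, {hi}]"
                )

    def default(self, name: str) -> float:
        return self.table[name][0]

    def lower(self, name: str) -> float:
        return self.table[name][1]

    def upper(self, name: str) -> float:
        return self.table[name][2]

    def arrays(self, names: Iterable[str]):
        names = list(names)
        import numpy as np

        x0 = np.array([self.default(n) for n in names])
        lo = np.array([self.lower(n) for n in names])
        hi = np.array([self.upper(n) for n in names])
        return x0, lo, hi

    def check(self, name: str, value: float) -> float:
        if name not in self.table:
            raise BoundsError(f"unknown parameter {name!r}")
        _, lo, hi = self.table[name]
        if not lo <= value <= hi:
            raise BoundsError(
                f"parameter {name!r} = {value} outside bounds [{lo}, {hi}]"
            )
        return float(value)


DEFAULT_BOUNDS = ParameterBounds()


def validate_params(
    values: Mapping[str, float] | None = None,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
) -> dict[str, float]:
    """Merge ``values`` over the defaults and enforce bounds.

    Returns the complete nine-parameter map.  Dependent stiffnesses are not
    accepted here; they are derived from the validated strains.
    """
    values = dict(values or {})
    out = {k: bounds.default(k) for k in PARAMETER_TABLE}
    for name, value in values.items():
        out[name] = bounds.check(name, value)
    # cross-parameter admissibility (also enforced by the curve constructors)
    if not out["eps_one_f"] > out["eps_zero_f"]:
        raise BoundsError(
            "eps_one_f must exceed eps_zero_f "
            f"({out['eps_one_f']} vs {out['eps_zero_f']})"
        )
    return out


def fibre_params_from(params: Mapping[str, float]) -> FibreCurveParams:
    return FibreCurveParams(
        eps_zero_f=params.get("eps_zero_f", DEFAULT_PARAMS["eps_zero_f"]),
        eps_one_f=params.get("eps_one_f", DEFAULT_PARAMS["eps_one_f"]),
        k_low_scale=params.get("k_low_scale", DEFAULT_PARAMS["k_low_scale"]),
        curviness_f=params.get("curviness_f", DEFAULT_PARAMS["curviness_f"]),
    )


def tendon_params_from(params: Mapping[str, float]) -> TendonCurveParams:
    return TendonCurveParams(
        eps_one_t=params.get("eps_one_t", DEFAULT_PARAMS["eps_one_t"]),
        f_toe_t=params.get("f_toe_t", DEFAULT_PARAMS["f_toe_t"]),
        curviness_t=params.get("curviness_t", DEFAULT_PARAMS["curviness_t"]),
    )


def read_param_file(path: str | Path) -> dict[str, float]:
    """Read a flat key-value parameter file (YAML mapping) and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return validate_params({k: float(v) for k, v in raw.items()})


def write_param_file(params: Mapping[str, float], path: str | Path) -> None:
    full = validate_params(params)
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in full.items()}, fh, sort_keys=False)
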