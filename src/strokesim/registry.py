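"""Model parameter registry: hazards, hazard ratios, treatment effects, costs, utilities.

Every tunable number in the simulation lives here as a named entry with a base
value and lower/upper uncertainty bounds, so one-way sensitivity analysis can
swing any parameter without touching code.  Validation happens at load time:
the engine never has to guard against a negative hazard or a relative risk
reduction above 1.

Naming conventions drive validation:

* ``h_*``      — annual hazards/rates, must be >= 0
* ``hr_*``     — hazard ratios (defined per *decrease* of the named unit), > 0
* ``rrr_*``    — relative risk reductions, in [0, 1)
* ``cost_*``   — 2022 U.S. dollars, >= 0
* ``u_base*``  — utility level in [0, 1]
* ``du_*``     — utility decrements, >= 0
* ``eff_*``    — per-rung treatment effects on risk factors, >= 0
* ``drift_*``  — annual natural-history slopes, any sign
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["Parameter", "ParameterRegistry", "RegistryError", "default_registry"]


class RegistryError(ValueError):
    """Raised when a parameter file fails validation."""


@dataclass(frozen=True)
class Parameter:
    """One named model input with base value and uncertainty bounds."""

    name: str
    base: float
    low: float
    high: float
    units: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise RegistryError(
                f"{self.name}: bounds must satisfy low <= base <= high "
                f"(got {self.low}, {self.base}, {self.high})"
            )


def _check_range(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise RegistryError(f"{name}: non-finite value {value}")
    if name.startswith(("h_", "cost_", "du_", "eff_")) and value < 0:
        raise RegistryError(f"{name}: must be >= 0, got {value}")
    if name.startswith("hr_") and value <= 0:
        raise RegistryError(f"{name}: hazard ratio must be > 0, got {value}")
    if name.startswith("rrr_") and not (0 <= value < 1):
        raise RegistryError(f"{name}: relative risk reduction must be in [0, 1), got {value}")
    if name.startswith("u_base") and not (0 <= value <= 1):
        raise RegistryError(f"{name}: utility must be in [0, 1], got {value}")
    if name.startswith("p_") and not (0 <= value <= 1):
        raise RegistryError(f"{name}: probability must be in [0, 1], got {value}")


@dataclass
class ParameterRegistry:
    """Validated mapping of parameter name -> :class:`Parameter`."""

    params: dict[str, Parameter] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for p in self.params.values():
            for v in (p.low, p.base, p.high):
                _check_range(p.name, v)

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.params[name]
        except KeyError:
            raise RegistryError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        """Base value of ``name``."""
        return self[name].base

    def bound(self, name: str, which: str) -> float:
        """Low or high bound of ``name`` (``which`` in {'low', 'high'})."""
        if which not in ("low", "high"):
            raise RegistryError(f"bound must be 'low' or 'high', got {which!r}")
        return getattr(self[name], which)

    def has_bounds(self, name: str) -> bool:
        p = self[name]
        return p.low != p.base or p.high != p.base

    def with_value(self, name: str, value: float) -> "ParameterRegistry":
        """Copy of the registry with ``name`` pinned to ``value`` (bounds collapse)."""
        _check_range(name, value)
        p = self[name]
        new = dict(self.params)
        new[name] = replace(p, base=value, low=min(p.low, value), high=max(p.high, value))
        return ParameterRegistry(params=new, version=self.version)

    def at_bound(self, name: str, which: str) -> "ParameterRegistry":
        """Copy with ``name`` set to its low/high bound, all else at base."""
        return self.with_value(name, self.bound(name, which))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_dict(cls, data: dict) -> "ParameterRegistry":
        version = str(data.get("version", "unversioned"))
        raw = data.get("parameters")
        if not isinstance(raw, dict) or not raw:
            raise RegistryError("registry file needs a non-empty 'parameters' mapping")
        params = {}
        for name, rec in raw.items():
            if not isinstance(rec, dict) or "base" not in rec:
                raise RegistryError(f"{name}: each parameter needs at least a 'base' value")
            base = float(rec["base"])
            params[name] = Parameter(
                name=name,
                base=base,
                low=float(rec.get("low", base)),
                high=float(rec.get("high", base)),
                units=str(rec.get("units", "")),
                note=str(rec.get("note", "")),
            )
        return cls(params=params, version=version)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "version": self.version,
            "parameters": {
                p.name: {
                    "base": p.base,
                    "low": p.low,
                    "high": p.high,
                    "units": p.units,
                    "note": p.note,
                }
                for p in self.params.values()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_registry() -> ParameterRegistry:
    """Load the registry shipped with the package."""
    ref = resources.files("strokesim.data").joinpath("default_registry.yaml")
    with resources.as_file(ref) as path:
        return ParameterRegistry.from_yaml(path)
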