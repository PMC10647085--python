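"""Unit dialects and exact conversions to canonical SI-aligned units.

Property values arrive as free text in a mix of unit spellings (°F, deg F,
mm Hg, torr, mg/L, ...).  This module maps provider spellings onto a closed
canonical unit set and converts values exactly:

================  ==================  ==============
dimension         canonical unit      examples
================  ==================  ==============
temperature       K                   °C, °F, deg C
pressure          kPa                 mmHg, atm, bar
mass concentr.    kg/m³               mg/L, mg/mL
density           kg/m³               g/cm³, g/mL
molar mass        g/mol               Da, amu
charge            e                   —
================  ==================  ==============

The alias table ships as a text config (``data/unit_aliases.toml``) and can be
extended at run time with :func:`register_alias`.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from typing import Iterable

__all__ = [
    "UnitError",
    "register_alias",
    "resolve_unit",
    "unit_dimension",
    "convert_temperature",
    "convert_pressure",
    "convert_linear",
    "to_canonical_value",
    "CANONICAL_UNIT_FOR_DIMENSION",
    "PROPERTY_DIMENSIONS",
    "NON_METRIC_UNITS",
]


class UnitError(ValueError):
    """Unknown unit spelling or a dimension mismatch."""


#: canonical unit symbol -> dimension name
_DIMENSION_OF: dict[str, str] = {
    "K": "temperature",
    "°C": "temperature",
    "°F": "temperature",
    "kPa": "pressure",
    "Pa": "pressure",
    "hPa": "pressure",
    "mmHg": "pressure",
    "atm": "pressure",
    "bar": "pressure",
    "mg/L": "mass_concentration",
    "g/L": "mass_concentration",
    "mg/mL": "mass_concentration",
    "g/mL": "mass_concentration",
    "kg/m³": "mass_concentration",
    "g/cm³": "density",
    "g/mol": "molar_mass",
    "kg/mol": "molar_mass",
    "Da": "molar_mass",
    "e": "charge",
}

CANONICAL_UNIT_FOR_DIMENSION: dict[str, str] = {
    "temperature": "K",
    "pressure": "kPa",
    "mass_concentration": "kg/m³",
    "density": "kg/m³",
    "molar_mass": "g/mol",
    "charge": "e",
}

#: property kind -> dimension; user code may register further kinds.
PROPERTY_DIMENSIONS: dict[str, str] = {
    "BoilingPoint": "temperature",
    "MeltingPoint": "temperature",
    "FlashPoint": "temperature",
    "AutoignitionTemperature": "temperature",
    "VaporPressure": "pressure",
    "Solubility": "mass_concentration",
    "Density": "density",
    "MolecularWeight": "molar_mass",
    "Charge": "charge",
}

#: value-unit spellings treated as non-metric when the curation stage prefers
#: metric originals (standard atmosphere dialects included).
NON_METRIC_UNITS: frozenset[str] = frozenset({"°F", "mmHg", "atm"})

# conversion factors for linear (purely multiplicative) units, per dimension,
# expressed in the dimension's canonical unit per source unit
_LINEAR_FACTOR: dict[str, float] = {
    "kPa": 1.0,
    "Pa": 1e-3,
    "hPa": 0.1,
    "mmHg": 101.325 / 760.0,  # standard atmosphere definition
    "atm": 101.325,
    "bar": 100.0,
    "mg/L": 1e-3,  # 1 mg/L = 1e-6 kg / 1e-3 m³
    "g/L": 1.0,
    "mg/mL": 1.0,
    "g/mL": 1000.0,
    "kg/m³": 1.0,
    "g/cm³": 1000.0,
    "g/mol": 1.0,
    "kg/mol": 1000.0,
    "Da": 1.0,
    "e": 1.0,
}

_ALIASES: dict[str, str] = {}
_ALIAS_VERSION = 0


def alias_version() -> int:
    """Counter bumped whenever the alias table changes (for regex caches)."""
    return _ALIAS_VERSION


def _load_default_aliases() -> None:
    data = resources.files("specieskg").joinpath("data/unit_aliases.toml").read_bytes()
    table = tomllib.loads(data.decode("utf-8"))
    for canonical, spellings in table["aliases"].items():
        if canonical not in _DIMENSION_OF:
            raise UnitError(f"alias target {canonical!r} is not a known unit")
        _ALIASES[canonical] = canonical
        for s in spellings:
            _ALIASES[s] = canonical


def register_alias(spelling: str, canonical: str) -> None:
    """Teach the resolver one extra provider spelling for a known unit."""
    global _ALIAS_VERSION
    if canonical not in _DIMENSION_OF:
        raise UnitError(f"{canonical!r} is not a known canonical unit")
    _ALIASES[spelling] = canonical
    _ALIAS_VERSION += 1


def known_spellings() -> Iterable[str]:
    return _ALIASES.keys()


def resolve_unit(spelling: str) -> str:
    """Map a provider unit spelling to its canonical symbol."""
    s = spelling.strip()
    if s in _ALIASES:
        return _ALIASES[s]
    raise UnitError(f"unknown unit {spelling!r}")


def unit_dimension(unit: str) -> str:
    return _DIMENSION_OF[resolve_unit(unit)]


def convert_temperature(value: float, unit: str) -> float:
    """Exact conversion to kelvin from K, °C or °F."""
    u = resolve_unit(unit)
    if u == "K":
        return float(value)
    if u == "°C":
        return float(value) + 273.15
    if u == "°F":
        return (float(value) - 32.0) * 5.0 / 9.0 + 273.15
    raise UnitError(f"{unit!r} is not a temperature unit")


def convert_pressure(value: float, unit: str) -> float:
    """Exact conversion to kilopascal (760 mmHg = 1 atm = 101.325 kPa)."""
    u = resolve_unit(unit)
    if _DIMENSION_OF[u] != "pressure":
        raise UnitError(f"{unit!r} is not a pressure unit")
    return float(value) * _LINEAR_FACTOR[u]


def convert_linear(value: float, unit: str) -> float:
    """Multiplicative conversion to the unit's dimension's canonical unit."""
    u = resolve_unit(unit)
    if u not in _LINEAR_FACTOR:
        raise UnitError(f"{unit!r} does not convert multiplicatively")
    return float(value) * _LINEAR_FACTOR[u]


def to_canonical_value(value: float, unit: str, dimension: str) -> tuple[float, str]:
    """Convert ``value unit`` to the canonical unit of ``dimension``.

    Raises :class:`UnitError` when the unit's dimension disagrees (a length
    offered as a boiling point, a temperature offered as a solubility, ...).
    Density accepts mass-concentration spellings — both target kg/m³.
    """
    u = resolve_unit(unit)
    udim = _DIMENSION_OF[u]
    compatible = {dimension}
    if dimension in ("density", "mass_concentration"):
        compatible = {"density", "mass_concentration"}
    if udim not in compatible:
        raise UnitError(f"unit {unit!r} ({udim}) does not measure {dimension}")
    target = CANONICAL_UNIT_FOR_DIMENSION[dimension]
    if dimension == "temperature":
        return convert_temperature(value, u), target
    return convert_linear(value, u), target


_load_default_aliases()
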