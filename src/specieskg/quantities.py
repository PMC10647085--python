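"""Free-text property strings → parsed quantities → canonical units.

Experimental property values are collected from many sources as strings with
wildly varying syntax: ``"134.4 °F at 760 mmHg (NTP, 1992)"``,
``"1,000,000 mg/L (at 25 °C)"``, ``"In water, miscible/1 × 10 + 6 mg/L/at
25 °C"``.  The parser extracts numeric quantities with their units, keeps
measurement conditions ("at 25 °C") separate from measured values, records
inequality/approximation qualifiers, and discards strings in which no numeric
value is found.  Canonicalization then rewrites every quantity into the
canonical unit of its property kind (temperature → K, pressure → kPa, mass
concentration → kg/m³, ...) so values from different sources are directly
comparable.

Handled dialects: scientific notation as ``1e6`` / ``1.0E+06`` / the spelled
form ``1 × 10 + 6``; thousands separators (``1,000,000``); parenthesized
citations (``(NTP, 1992)``) and estimation tags (``(est)``).  Decimal commas
are not supported and such strings are discarded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from datetime import datetime
from typing import Optional, Sequence

from . import units
from .model import PropertyRecord, Provenance, ReferenceState
from .units import UnitError

__all__ = [
    "Condition",
    "ParsedQuantity",
    "CanonicalizationError",
    "parse_property_string",
    "to_canonical",
    "build_property_record",
    "records_from_strings",
]

log = logging.getLogger(__name__)

QUALIFIERS = ("none", "at_least", "at_most", "approx")


@dataclass(frozen=True)
class Condition:
    """A measurement condition such as ``at 25 °C`` or ``@ 760 mmHg``."""

    quantity_kind: str  # "temperature", "pressure", or another dimension name
    value: float
    unit: str


@dataclass(frozen=True)
class ParsedQuantity:
    value: float
    unit: str
    qualifier: str = "none"
    conditions: tuple[Condition, ...] = ()
    source_string: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")


class CanonicalizationError(ValueError):
    """Unit incompatible with the property kind's dimension."""


_NUMBER = r"[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?"

# "1 × 10 + 6", "1.5 x 10^-3", "2×10+4" → e-notation
_SPELLED_SCI = re.compile(
    rf"({_NUMBER})\s*[×x*]\s*10\s*\^?\s*([+-]?)\s*(\d+)"
)
_THOUSANDS = re.compile(r"(?<=\d),(?=\d\d\d(?:\D|$))")
_PARENTHETICAL = re.compile(r"\(([^()]*)\)")

_QUALIFIER_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"greater\s+than\s+or\s+equal\s+to|not\s+less\s+than|>=|≥", "at_least"),
    (r"less\s+than\s+or\s+equal\s+to|not\s+more\s+than|<=|≤", "at_most"),
    (r"greater\s+than|more\s+than|>", "at_least"),
    (r"less\s+than|<", "at_most"),
    (r"~|≈|\bca\.|\bcirca\b|\bapprox(?:\.|imately)?\b|\best(?:\.|imated)?\b", "approx"),
)

_COMMA_DECIMAL = re.compile(r"\d+,\d{1,2}(?:\D|$)")


import functools


@functools.lru_cache(maxsize=8)
def _unit_regex_for(version: int) -> re.Pattern[str]:
    spellings = sorted(units.known_spellings(), key=len, reverse=True)
    alternation = "|".join(re.escape(s) for s in spellings)
    # unit must not be glued to a following letter ("100 ms" must not read "m")
    return re.compile(rf"({_NUMBER})\s*({alternation})(?![A-Za-z0-9²³])")


def _unit_regex() -> re.Pattern[str]:
    return _unit_regex_for(units.alias_version())


def _prepare(text: str) -> tuple[str, str]:
    """Normalize dialects; return (normalized text, qualifier)."""
    s = text
    qualifier = "none"
    for pattern, q in _QUALIFIER_PATTERNS:
        if re.search(pattern, s, flags=re.IGNORECASE):
            qualifier = q
            break

    # parentheticals: inline condition-bearing ones, drop citations/tags
    def _paren(m: re.Match[str]) -> str:
        content = m.group(1)
        if _unit_regex().search(_THOUSANDS.sub("", content)):
            return " " + content + " "
        return " "

    s = _PARENTHETICAL.sub(_paren, s)
    s = _THOUSANDS.sub("", s)
    s = _SPELLED_SCI.sub(lambda m: f"{m.group(1)}e{m.group(2) or '+'}{m.group(3)}", s)
    return s, qualifier


def parse_property_string(text: str) -> list[ParsedQuantity]:
    """Extract quantities from one raw property string.

    Returns an empty list when no numeric value with a recognizable unit is
    found; the caller is expected to discard the string in that case.  A
    quantity preceded by "at"/"@" is a measurement condition, not a value;
    all conditions found in the string are attached to every extracted value.
    """
    if not text:
        return []
    if _COMMA_DECIMAL.search(_THOUSANDS.sub("", text)):
        log.info("discarding %r: decimal commas are not supported", text)
        return []
    s, qualifier = _prepare(text)

    values: list[tuple[float, str]] = []
    conditions: list[Condition] = []
    for m in _unit_regex().finditer(s):
        value = float(m.group(1))
        unit = units.resolve_unit(m.group(2))
        prefix = s[: m.start()].rstrip()
        if re.search(r"(?:\bat|@)$", prefix, flags=re.IGNORECASE):
            dim = units.unit_dimension(unit)
            conditions.append(Condition(dim, value, unit))
        else:
            values.append((value, unit))
    return [
        ParsedQuantity(
            value=v,
            unit=u,
            qualifier=qualifier,
            conditions=tuple(conditions),
            source_string=text,
        )
        for v, u in values
    ]


def to_canonical(q: ParsedQuantity, kind: str) -> ParsedQuantity:
    """Rewrite a quantity (and its conditions) into the kind's canonical unit.

    Idempotent; raises :class:`CanonicalizationError` on dimension mismatch or
    unknown property kind.
    """
    dim = units.PROPERTY_DIMENSIONS.get(kind)
    if dim is None:
        raise CanonicalizationError(f"no dimension registered for property kind {kind!r}")
    try:
        value, unit = units.to_canonical_value(q.value, q.unit, dim)
    except UnitError as exc:
        raise CanonicalizationError(str(exc)) from exc
    conditions = []
    for c in q.conditions:
        if c.quantity_kind == "temperature":
            conditions.append(Condition("temperature", units.convert_temperature(c.value, c.unit), "K"))
        elif c.quantity_kind == "pressure":
            conditions.append(Condition("pressure", units.convert_pressure(c.value, c.unit), "kPa"))
        else:
            conditions.append(c)
    return replace(q, value=value, unit=unit, conditions=tuple(conditions))


def _reference_state(q: ParsedQuantity, kind: str) -> Optional[ReferenceState]:
    """Pick the reference state among the quantity's conditions.

    Temperature-valued properties (boiling point, ...) take their pressure
    condition; everything else prefers the temperature condition.
    """
    by_kind = {c.quantity_kind: c for c in q.conditions}
    dim = units.PROPERTY_DIMENSIONS.get(kind)
    order = ("pressure", "temperature") if dim == "temperature" else ("temperature", "pressure")
    for k in order:
        if k in by_kind:
            c = by_kind[k]
            return ReferenceState(quantity_kind=k, value=c.value, unit=c.unit)
    return None


def build_property_record(
    q: ParsedQuantity,
    kind: str,
    index: int,
    provenance: Provenance,
    date_acquired: Optional[datetime] = None,
) -> PropertyRecord:
    """Materialize a canonical quantity as a property record.

    ``q`` must already be canonical (see :func:`to_canonical`); the record
    keeps the verbatim source string and derives its reference state from the
    parsed conditions (temperature/pressure only).
    """
    dim = units.PROPERTY_DIMENSIONS.get(kind)
    if dim is not None and q.unit != units.CANONICAL_UNIT_FOR_DIMENSION[dim]:
        raise CanonicalizationError(
            f"quantity for {kind} must be canonicalized first (got unit {q.unit!r})"
        )
    return PropertyRecord(
        kind=kind,
        index=index,
        value=q.value,
        unit=q.unit,
        provenance=provenance,
        original_string=q.source_string or None,
        date_acquired=date_acquired,
        reference_state=_reference_state(q, kind),
        is_recommended=False,
    )


def records_from_strings(
    kind: str,
    entries: Sequence[tuple[str, Provenance]],
    *,
    start_index: int = 1,
    date_acquired: Optional[datetime] = None,
) -> tuple[list[PropertyRecord], list[tuple[str, str]]]:
    """Run the full parse → canonicalize → record pipeline over raw strings.

    Returns ``(records, discarded)`` where ``discarded`` pairs each rejected
    string with the reason ("no numeric value", "faulty unit: ...").  Discards
    are also logged.  Indices continue consecutively from ``start_index``.
    """
    records: list[PropertyRecord] = []
    discarded: list[tuple[str, str]] = []
    index = start_index
    for text, provenance in entries:
        quantities = parse_property_string(text)
        if not quantities:
            reason = "no numerical value detected"
            log.info("discarding %s string %r: %s", kind, text, reason)
            discarded.append((text, reason))
            continue
        for q in quantities:
            try:
                canonical = to_canonical(q, kind)
            except CanonicalizationError as exc:
                reason = f"faulty unit: {exc}"
                log.info("discarding %s quantity from %r: %s", kind, text, reason)
                discarded.append((text, reason))
                continue
            records.append(
                build_property_record(
                    canonical, kind, index, provenance, date_acquired=date_acquired
                )
            )
            index += 1
    return records, discarded
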