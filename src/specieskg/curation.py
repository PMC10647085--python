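"""Recommended-value selection and discrepancy flagging.

When several sources report the same property, the curation agent groups
approximately equal values (single-linkage on relative distance), picks the
largest group, and selects one representative value using a deterministic
preference policy: metric original strings beat non-metric ones, more decimal
places in the original numeric token beat fewer, lowest index breaks any
remaining tie.  The selected value is stored as a new record flagged
``is_recommended`` with the curation agent's provenance label.  Records that
deviate from the recommended value by more than a relative threshold (default
20%) are flagged as discrepant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence, TextIO

from .model import (
    PropertyRecord,
    Provenance,
    RECOMMENDED_PROVENANCE_LABEL,
)
from .quantities import parse_property_string
from .units import NON_METRIC_UNITS

__all__ = [
    "ValueGroup",
    "group_equivalent",
    "select_recommended",
    "flag_discrepant",
    "format_audit_report",
    "write_audit_report",
]


@dataclass(frozen=True)
class ValueGroup:
    """Indices (into the input list) of approximately equal records."""

    member_indices: frozenset[int]
    center: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_indices", frozenset(self.member_indices))


def _rel_distance(a: float, b: float) -> float:
    lo = min(abs(a), abs(b))
    if lo == 0.0:
        return 0.0 if a == b else float("inf")
    return abs(a - b) / lo


def group_equivalent(
    records: Sequence[PropertyRecord], rel_tol: float
) -> list[ValueGroup]:
    """Single-linkage grouping on relative distance ≤ ``rel_tol``.

    The result partitions the records; groups are ordered by their smallest
    member index, so the output is deterministic in the input order.
    """
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must lie in (0, 1)")
    units_seen = {r.unit for r in records}
    if len(units_seen) > 1:
        raise ValueError(f"records mix units: {sorted(units_seen)}")
    kinds = {r.kind for r in records}
    if len(kinds) > 1:
        raise ValueError(f"records mix property kinds: {sorted(kinds)}")

    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _rel_distance(records[i].value, records[j].value) <= rel_tol:
                parent[find(i)] = find(j)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(i)
    groups = [
        ValueGroup(frozenset(m), median(records[i].value for i in m))
        for m in members.values()
    ]
    return sorted(groups, key=lambda g: min(g.member_indices))


_FIRST_NUMBER = re.compile(r"\d+(?:\.(\d+))?")


def _decimal_places(record: PropertyRecord) -> int:
    """Decimal places of the first numeric token of the original string.

    Records without an original string fall back to the canonical value's
    shortest decimal representation.
    """
    text = record.original_string
    if text is None:
        text = repr(record.value)
    m = _FIRST_NUMBER.search(text.replace(",", ""))
    if m is None or m.group(1) is None:
        return 0
    return len(m.group(1))


def _is_metric_original(record: PropertyRecord) -> bool:
    """True unless the original string's value unit is a non-metric spelling."""
    if record.original_string is None:
        return True
    parsed = parse_property_string(record.original_string)
    if not parsed:
        return True
    return parsed[0].unit not in NON_METRIC_UNITS


def select_recommended(
    records: Sequence[PropertyRecord], rel_tol: float = 0.10
) -> PropertyRecord:
    """Select the recommended value among canonical records of one kind.

    Policy: (1) group approximately equal values; (2) the winning group is the
    largest, ties broken by the group center closest to the global median;
    (3) within the winner prefer metric originals, then the original numeric
    token with the most decimal places, then the lowest index.  The result is
    a **new** record (index continuing after the inputs) with
    ``is_recommended=True`` and the curation agent's provenance label.
    """
    if not records:
        raise ValueError("select_recommended needs at least one record")
    candidates = [r for r in records if not r.is_recommended]
    if not candidates:
        raise ValueError("no non-recommended input records")
    groups = group_equivalent(candidates, rel_tol)
    global_median = median(r.value for r in candidates)
    winner = min(
        groups,
        key=lambda g: (
            -len(g.member_indices),
            abs(g.center - global_median),
            min(g.member_indices),
        ),
    )
    chosen_i = min(
        winner.member_indices,
        key=lambda i: (
            not _is_metric_original(candidates[i]),
            -_decimal_places(candidates[i]),
            i,
        ),
    )
    chosen = candidates[chosen_i]
    next_index = max(r.index for r in records) + 1
    return PropertyRecord(
        kind=chosen.kind,
        index=next_index,
        value=chosen.value,
        unit=chosen.unit,
        provenance=Provenance(label=RECOMMENDED_PROVENANCE_LABEL),
        is_recommended=True,
    )


def flag_discrepant(
    records: Iterable[PropertyRecord],
    recommended: PropertyRecord,
    rel_threshold: float = 0.20,
) -> list[PropertyRecord]:
    """Records deviating from the recommended value by strictly more than
    ``rel_threshold`` (relative to the recommended value)."""
    if recommended.value <= 0:
        raise ValueError("recommended value must be positive")
    flagged = []
    for r in records:
        if r is recommended or r.is_recommended:
            continue
        if abs(r.value - recommended.value) / recommended.value > rel_threshold:
            flagged.append(r)
    return flagged


def format_audit_report(
    flagged: Sequence[tuple[str, PropertyRecord]]
) -> str:
    """Tabular (TSV) report of discrepant records.

    One row per flagged record: species IRI, property kind, value, unit,
    provenance locator (or label when no locator is recorded).
    """
    lines = ["species_iri\tproperty\tvalue\tunit\tprovenance"]
    for species_iri, r in flagged:
        source = r.provenance.locator or r.provenance.label
        lines.append(f"{species_iri}\t{r.kind}\t{r.value:g}\t{r.unit}\t{source}")
    return "\n".join(lines) + "\n"


def write_audit_report(
    flagged: Sequence[tuple[str, PropertyRecord]], stream: TextIO
) -> None:
    stream.write(format_audit_report(flagged))
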