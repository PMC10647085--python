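"""Structural shape constraints for emitted graphs.

Every graph committed to a :class:`~specieskg.store.SpeciesStore` must
conform: species carry exactly one label and at least one identifier,
property nodes carry value/unit/provenance, recommended values carry the
curation agent's provenance label, bond orders are positive integers, and
peaks have positions.  The validator is implemented natively over rdflib and
returns a report of (focus node, shape id, message) violations; an equivalent
SHACL document is shipped (``data/shapes.ttl``) for use with external SHACL
processors.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, InvalidOperation

from rdflib import Graph, Literal

from . import vocab as V
from .model import RECOMMENDED_PROVENANCE_LABEL
from .vocab import RDF, RDFS

__all__ = ["ValidationReport", "validate_shapes"]


@dataclass(frozen=True)
class ValidationReport:
    conforms: bool
    violations: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "violations", tuple(self.violations))
        assert self.conforms == (len(self.violations) == 0)


def _is_decimal(lit) -> bool:
    try:
        Decimal(str(lit))
        return True
    except InvalidOperation:
        return False


def validate_shapes(graph: Graph) -> ValidationReport:
    """Check the shipped shape set over a graph; never raises."""
    violations: list[tuple[str, str, str]] = []

    def violate(focus, shape: str, message: str) -> None:
        violations.append((str(focus), shape, message))

    for s in graph.subjects(RDF.type, V.SPECIES):
        labels = list(graph.objects(s, RDFS.label))
        if len(labels) != 1:
            violate(s, "SpeciesLabelShape",
                    f"species must have exactly one rdfs:label, found {len(labels)}")
        if next(graph.objects(s, V.HAS_IDENTIFIER), None) is None:
            violate(s, "SpeciesIdentifierShape",
                    "species must have at least one identifier")

    for p in graph.subjects(RDF.type, V.PROPERTY):
        value = graph.value(p, V.VALUE)
        if value is None:
            violate(p, "PropertyValueShape", "property node lacks os:value")
        elif not isinstance(value, Literal) or not _is_decimal(value):
            violate(p, "PropertyValueShape", "os:value must be a decimal literal")
        if graph.value(p, V.UNIT) is None:
            violate(p, "PropertyUnitShape", "property node lacks os:unit")
        if graph.value(p, V.HAS_PROVENANCE) is None:
            violate(p, "PropertyProvenanceShape", "property node lacks os:hasProvenance")
        rec = graph.value(p, V.IS_RECOMMENDED)
        if rec is not None and bool(rec.toPython()):
            prov = graph.value(p, V.HAS_PROVENANCE)
            label = graph.value(prov, RDFS.label) if prov is not None else None
            if label is None or str(label) != RECOMMENDED_PROVENANCE_LABEL:
                violate(p, "RecommendedProvenanceShape",
                        "recommended property must carry provenance label "
                        f"{RECOMMENDED_PROVENANCE_LABEL!r}")

    for b in graph.subjects(RDF.type, V.ATOMIC_BOND):
        order = graph.value(b, V.HAS_BOND_ORDER)
        if order is None:
            violate(b, "BondOrderShape", "bond lacks os:hasBondOrder")
        else:
            try:
                ok = int(str(order)) >= 1 and "." not in str(order)
            except ValueError:
                ok = False
            if not ok:
                violate(b, "BondOrderShape",
                        f"bond order must be a positive integer, got {order}")

    for pk in graph.subjects(RDF.type, V.PEAK):
        if graph.value(pk, V.VALUE) is None:
            violate(pk, "PeakPositionShape", "peak lacks a position (os:value)")

    return ValidationReport(conforms=not violations, violations=tuple(violations))
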