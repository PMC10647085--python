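"""Embedded RDF store: triple emission, loading, and SPARQL query patterns.

:func:`emit_species_triples` materializes a :class:`~specieskg.model.Species`
as RDF triples following the ABox IRI conventions; :func:`load_species` is its
exact inverse (``load(emit(s)) == s``).  :class:`SpeciesStore` wraps an
in-memory rdflib graph, validates every emission against the shipped shape
constraints before committing, and provides the domain query patterns
(class-hierarchy descent, boiling points by class).
"""

from __future__ import annotations

from datetime import datetime
from decimal import Decimal
from pathlib import Path
from typing import Optional, Union

from rdflib import Graph, Literal, URIRef

from . import vocab as V
from .iri import (
    DEFAULT_NAMESPACE,
    mint_attached_iri,
    mint_free_iri,
    mint_species_iri,
    stable_id,
)
from .model import (
    Atom,
    AtomicBond,
    ChemicalClass,
    GHSStatement,
    IdentifierRecord,
    Peak,
    PropertyRecord,
    Provenance,
    ReferenceState,
    Species,
    SpectrumRecord,
    parse_formula,
)
from .shapes import ValidationReport, validate_shapes
from .vocab import RDF, RDFS, SKOS, XSD

__all__ = [
    "emit_species_triples",
    "load_species",
    "SpeciesStore",
    "boiling_by_class_query",
    "StoreError",
]


class StoreError(ValueError):
    pass


def _decimal(value: float) -> Literal:
    # Decimal via the float's shortest repr: lossless float -> decimal -> float
    return Literal(Decimal(repr(float(value))), datatype=XSD.decimal)


def _provenance_iri(p: Provenance, ns: str) -> URIRef:
    return URIRef(mint_free_iri("Reference", stable_id(p.label, p.locator or ""), ns))


def _emit_provenance(g: Graph, p: Provenance, ns: str) -> URIRef:
    node = _provenance_iri(p, ns)
    g.add((node, RDF.type, V.REFERENCE))
    if p.label:
        g.add((node, RDFS.label, Literal(p.label)))
    if p.locator:
        g.add((node, V.LOCATOR, Literal(p.locator)))
    return node


def _emit_class(g: Graph, c: ChemicalClass) -> URIRef:
    node = URIRef(c.iri)
    g.add((node, RDF.type, V.CHEMICAL_CLASS))
    g.add((node, RDFS.label, Literal(c.label)))
    if c.source_id:
        g.add((node, V.SOURCE_IDENTIFIER, Literal(c.source_id)))
    for parent in sorted(c.parents):
        g.add((node, V.HAS_PARENT_CLASS, URIRef(parent)))
    return node


def emit_species_triples(
    species: Species, namespace: str = DEFAULT_NAMESPACE
) -> Graph:
    """One triple per fact of the species, on a fresh graph."""
    g = Graph()
    g.bind("os", V.OS)
    g.bind("oskg", namespace)
    g.bind("skos", SKOS)
    uuid = species.uuid
    s = URIRef(mint_species_iri(uuid, namespace))
    g.add((s, RDF.type, V.SPECIES))
    g.add((s, RDFS.label, Literal(species.label)))
    for alt in sorted(species.alt_labels):
        g.add((s, SKOS.altLabel, Literal(alt)))

    for atom in species.atoms:
        a = URIRef(mint_attached_iri("Atom", atom.index, uuid, namespace))
        g.add((s, V.HAS_ATOM, a))
        g.add((a, RDF.type, V.ATOM))
        g.add((a, V.ATOM_INDEX, Literal(atom.index)))
        g.add((a, V.ELEMENT, Literal(atom.element)))
        for pred, coord in (
            (V.X_COORDINATE, atom.x),
            (V.Y_COORDINATE, atom.y),
            (V.Z_COORDINATE, atom.z),
        ):
            if coord is not None:
                g.add((a, pred, _decimal(coord)))

    for i, bond in enumerate(species.bonds, start=1):
        b = URIRef(mint_attached_iri("AtomicBond", i, uuid, namespace))
        g.add((s, V.HAS_ATOMIC_BOND, b))
        g.add((b, RDF.type, V.ATOMIC_BOND))
        g.add((b, V.BOND_ATOM_A, Literal(bond.atom_a)))
        g.add((b, V.BOND_ATOM_B, Literal(bond.atom_b)))
        g.add((b, V.HAS_BOND_ORDER, Literal(bond.order)))

    kind_counts: dict[str, int] = {}
    for ident in species.identifiers:
        kind_counts[ident.kind] = kind_counts.get(ident.kind, 0) + 1
        node = URIRef(
            mint_attached_iri(ident.kind, kind_counts[ident.kind], uuid, namespace)
        )
        g.add((s, V.HAS_IDENTIFIER, node))
        g.add((node, RDF.type, V.IDENTIFIER))
        g.add((node, RDF.type, V.OS[ident.kind]))
        g.add((node, V.VALUE, Literal(ident.value)))
        g.add((node, V.HAS_PROVENANCE, _emit_provenance(g, ident.provenance, namespace)))

    for rec in species.properties:
        node = URIRef(mint_attached_iri(rec.kind, rec.index, uuid, namespace))
        g.add((s, V.HAS_PROPERTY, node))
        g.add((node, RDF.type, V.PROPERTY))
        g.add((node, RDF.type, V.OS[rec.kind]))
        g.add((node, V.VALUE, _decimal(rec.value)))
        g.add((node, V.UNIT, Literal(rec.unit)))
        g.add((node, V.IS_RECOMMENDED, Literal(rec.is_recommended)))
        g.add((node, V.HAS_PROVENANCE, _emit_provenance(g, rec.provenance, namespace)))
        if rec.original_string is not None:
            g.add((node, V.ORIGINAL_DATA_STRING, Literal(rec.original_string)))
        if rec.date_acquired is not None:
            g.add(
                (node, V.DATE_OF_ACQUISITION,
                 Literal(rec.date_acquired, datatype=XSD.dateTime))
            )
        if rec.reference_state is not None:
            rs = URIRef(
                mint_attached_iri(
                    f"{rec.kind}ReferenceState", rec.index, uuid, namespace
                )
            )
            g.add((node, V.HAS_REFERENCE_STATE, rs))
            g.add((rs, RDF.type, V.REFERENCE_STATE))
            g.add((rs, V.QUANTITY_KIND, Literal(rec.reference_state.quantity_kind)))
            g.add((rs, V.VALUE, _decimal(rec.reference_state.value)))
            g.add((rs, V.UNIT, Literal(rec.reference_state.unit)))

    for c in species.classes:
        _emit_class(g, c)
        g.add((s, V.HAS_CHEMICAL_CLASS, URIRef(c.iri)))

    for i, ghs in enumerate(species.ghs_statements, start=1):
        node = URIRef(mint_attached_iri("GHSHazardStatement", i, uuid, namespace))
        g.add((s, V.HAS_GHS_STATEMENT, node))
        g.add((node, RDF.type, V.GHS_HAZARD_STATEMENT))
        g.add((node, V.VALUE, Literal(ghs.code)))
        if ghs.text:
            g.add((node, RDFS.label, Literal(ghs.text)))

    for use in species.uses:
        node = URIRef(mint_free_iri("Use", stable_id(use), namespace))
        g.add((s, V.HAS_USE, node))
        g.add((node, RDF.type, V.USE))
        g.add((node, RDFS.label, Literal(use)))

    for spec in species.spectra:
        class_name, tbox_class = V.SPECTRUM_CLASSES[spec.kind]
        node = URIRef(
            mint_attached_iri(class_name, spec.sequence_number, uuid, namespace)
        )
        g.add((s, V.HAS_SPECTRAL_INFORMATION, node))
        g.add((node, RDF.type, V.SPECTRAL_INFORMATION))
        g.add((node, RDF.type, tbox_class))
        g.add((node, V.SEQUENCE_NUMBER, Literal(spec.sequence_number)))
        if spec.solvent is not None:
            g.add((node, V.SOLVENT, Literal(spec.solvent)))
        if spec.frequency is not None:
            g.add((node, V.FREQUENCY, _decimal(spec.frequency)))
        if spec.ionization_mode is not None:
            g.add((node, V.IONIZATION_MODE, Literal(spec.ionization_mode)))
        for k, peak in enumerate(spec.peaks, start=1):
            p = URIRef(
                f"{namespace}Peak_{class_name}_{spec.sequence_number}_{k}"
                f"_Species_{uuid}"
            )
            g.add((node, V.HAS_PEAK, p))
            g.add((p, RDF.type, V.PEAK))
            g.add((p, V.VALUE, _decimal(peak.position)))
            g.add((p, V.INTENSITY, _decimal(peak.intensity)))
            if peak.multiplicity is not None:
                g.add((p, V.MULTIPLICITY, Literal(peak.multiplicity)))
    return g


def _opt_str(g: Graph, s: URIRef, p: URIRef) -> Optional[str]:
    v = g.value(s, p)
    return None if v is None else str(v)


def _opt_float(g: Graph, s: URIRef, p: URIRef) -> Optional[float]:
    v = g.value(s, p)
    return None if v is None else float(str(v))


def _load_provenance(g: Graph, node: URIRef) -> Provenance:
    return Provenance(
        label=_opt_str(g, node, RDFS.label) or "",
        locator=_opt_str(g, node, V.LOCATOR),
    )


def _property_kind(g: Graph, node: URIRef) -> str:
    for t in g.objects(node, RDF.type):
        if t != V.PROPERTY and str(t).startswith(str(V.OS)):
            return str(t)[len(str(V.OS)):]
    raise StoreError(f"property node {node} lacks a kind class")


def load_species(source: Union[Graph, "SpeciesStore"], species_iri: str) -> Species:
    """Reconstruct a :class:`Species` from its subgraph (inverse of emit)."""
    g = source.graph if isinstance(source, SpeciesStore) else source
    s = URIRef(species_iri)
    if (s, RDF.type, V.SPECIES) not in g:
        raise StoreError(f"{species_iri} is not a species in this graph")
    label = g.value(s, RDFS.label)
    if label is None:
        raise StoreError(f"{species_iri} lacks the mandatory rdfs:label")
    uuid = species_iri.rsplit("Species_", 1)[-1]

    atoms = []
    for a in g.objects(s, V.HAS_ATOM):
        atoms.append(
            Atom(
                index=int(g.value(a, V.ATOM_INDEX)),
                element=str(g.value(a, V.ELEMENT)),
                x=_opt_float(g, a, V.X_COORDINATE),
                y=_opt_float(g, a, V.Y_COORDINATE),
                z=_opt_float(g, a, V.Z_COORDINATE),
            )
        )
    bonds = []
    for b in g.objects(s, V.HAS_ATOMIC_BOND):
        bonds.append(
            AtomicBond(
                atom_a=int(g.value(b, V.BOND_ATOM_A)),
                atom_b=int(g.value(b, V.BOND_ATOM_B)),
                order=int(g.value(b, V.HAS_BOND_ORDER)),
            )
        )
    identifiers = []
    for node in g.objects(s, V.HAS_IDENTIFIER):
        kind = None
        for t in g.objects(node, RDF.type):
            if t != V.IDENTIFIER and str(t).startswith(str(V.OS)):
                kind = str(t)[len(str(V.OS)):]
        identifiers.append(
            IdentifierRecord(
                kind=kind or "Identifier",
                value=str(g.value(node, V.VALUE)),
                provenance=_load_provenance(g, g.value(node, V.HAS_PROVENANCE)),
            )
        )
    properties = []
    for node in g.objects(s, V.HAS_PROPERTY):
        rs_node = g.value(node, V.HAS_REFERENCE_STATE)
        reference_state = None
        if rs_node is not None:
            reference_state = ReferenceState(
                quantity_kind=str(g.value(rs_node, V.QUANTITY_KIND)),
                value=float(str(g.value(rs_node, V.VALUE))),
                unit=str(g.value(rs_node, V.UNIT)),
            )
        date_lit = g.value(node, V.DATE_OF_ACQUISITION)
        date_acquired = date_lit.toPython() if date_lit is not None else None
        if isinstance(date_acquired, str):  # pragma: no cover - malformed input
            date_acquired = datetime.fromisoformat(date_acquired)
        properties.append(
            PropertyRecord(
                kind=_property_kind(g, node),
                index=int(str(node).rsplit("_Species_", 1)[0].rsplit("_", 1)[-1]),
                value=float(str(g.value(node, V.VALUE))),
                unit=str(g.value(node, V.UNIT)),
                provenance=_load_provenance(g, g.value(node, V.HAS_PROVENANCE)),
                original_string=_opt_str(g, node, V.ORIGINAL_DATA_STRING),
                date_acquired=date_acquired,
                reference_state=reference_state,
                is_recommended=bool(g.value(node, V.IS_RECOMMENDED).toPython()),
            )
        )
    classes = []
    for c in g.objects(s, V.HAS_CHEMICAL_CLASS):
        classes.append(
            ChemicalClass(
                iri=str(c),
                label=_opt_str(g, c, RDFS.label) or "",
                parents=frozenset(str(p) for p in g.objects(c, V.HAS_PARENT_CLASS)),
                source_id=_opt_str(g, c, V.SOURCE_IDENTIFIER),
            )
        )
    ghs = []
    for node in g.objects(s, V.HAS_GHS_STATEMENT):
        ghs.append(
            GHSStatement(
                code=str(g.value(node, V.VALUE)),
                text=_opt_str(g, node, RDFS.label) or "",
            )
        )
    uses = [str(g.value(u, RDFS.label)) for u in g.objects(s, V.HAS_USE)]
    spectra = []
    kind_by_class = {tbox: kind for kind, (_, tbox) in V.SPECTRUM_CLASSES.items()}
    for node in g.objects(s, V.HAS_SPECTRAL_INFORMATION):
        kind = None
        for t in g.objects(node, RDF.type):
            if t in kind_by_class:
                kind = kind_by_class[t]
        peaks = sorted(
            g.objects(node, V.HAS_PEAK),
            key=lambda p: int(str(p).rsplit("_Species_", 1)[0].rsplit("_", 1)[-1]),
        )
        spectra.append(
            SpectrumRecord(
                kind=kind or "NMR1D",
                peaks=tuple(
                    Peak(
                        position=float(str(g.value(p, V.VALUE))),
                        intensity=float(str(g.value(p, V.INTENSITY))),
                        multiplicity=_opt_str(g, p, V.MULTIPLICITY),
                    )
                    for p in peaks
                ),
                sequence_number=int(g.value(node, V.SEQUENCE_NUMBER)),
                solvent=_opt_str(g, node, V.SOLVENT),
                frequency=_opt_float(g, node, V.FREQUENCY),
                ionization_mode=_opt_str(g, node, V.IONIZATION_MODE),
            )
        )
    return Species(
        uuid=uuid,
        formula=parse_formula(str(label)),
        alt_labels=frozenset(str(x) for x in g.objects(s, SKOS.altLabel)),
        atoms=atoms,
        bonds=bonds,
        identifiers=identifiers,
        properties=properties,
        classes=classes,
        ghs_statements=ghs,
        uses=uses,
        spectra=spectra,
    )


def boiling_by_class_query(class_label: str) -> str:
    """SPARQL text for the boiling-point-by-class pattern (hierarchy descent).

    Returns species label, boiling-point value and the optional reference
    pressure in kPa; user-facing documentation parity for the trend queries.
    """
    return f"""
PREFIX os: <{V.OS}>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?species ?label ?value ?refPressure WHERE {{
  ?cls a os:ChemicalClass ; rdfs:label "{class_label}" .
  ?sub os:hasParentClass* ?cls .
  ?species os:hasChemicalClass ?sub ;
           rdfs:label ?label ;
           os:hasProperty ?bp .
  ?bp a os:BoilingPoint ; os:value ?value .
  OPTIONAL {{
    ?bp os:hasReferenceState ?rs .
    ?rs os:quantityKind "pressure" ; os:value ?refPressure .
  }}
}}
"""


class SpeciesStore:
    """In-memory triple store with validation-gated commits."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE) -> None:
        self.namespace = namespace
        self.graph = Graph()
        self.graph.bind("os", V.OS)
        self.graph.bind("oskg", namespace)
        self.graph.bind("skos", SKOS)

    # -- persistence -------------------------------------------------------
    @classmethod
    def from_turtle(
        cls, path: Union[str, Path], namespace: str = DEFAULT_NAMESPACE
    ) -> "SpeciesStore":
        store = cls(namespace)
        store.graph.parse(str(path), format="turtle")
        return store

    def save_turtle(self, path: Union[str, Path]) -> None:
        self.graph.serialize(destination=str(path), format="turtle")

    # -- writes ------------------------------------------------------------
    def add_species(self, species: Species) -> str:
        """Emit, validate, and commit one species; returns its IRI."""
        g = emit_species_triples(species, self.namespace)
        report = validate_shapes(g)
        if not report.conforms:
            raise StoreError(
                "refusing to commit non-conforming species: "
                + "; ".join(m for _, _, m in report.violations)
            )
        self.graph += g
        return mint_species_iri(species.uuid, self.namespace)

    def ensure_class(self, c: ChemicalClass) -> str:
        _emit_class(self.graph, c)
        return c.iri

    def add_class_assertion(self, species_iri: str, class_iri: str) -> None:
        """Tag a species with a class; idempotent (set semantics)."""
        s, c = URIRef(species_iri), URIRef(class_iri)
        if (s, None, None) not in self.graph:
            raise StoreError(f"unknown species node {species_iri}")
        if (c, None, None) not in self.graph:
            raise StoreError(f"unknown class node {class_iri}")
        self.graph.add((s, V.HAS_CHEMICAL_CLASS, c))

    # -- reads -------------------------------------------------------------
    def sparql(self, query_text: str):
        """Run a SPARQL 1.1 query; syntax errors are surfaced with position."""
        return self.graph.query(query_text)

    def species_iris(self) -> list[str]:
        return sorted(str(s) for s in self.graph.subjects(RDF.type, V.SPECIES))

    def load_species(self, species_iri: str) -> Species:
        return load_species(self.graph, species_iri)

    def find_species_by_identifier(self, value: str) -> Optional[str]:
        """Species IRI whose identifier has exactly this value, if any."""
        for node in self.graph.subjects(V.VALUE, Literal(value)):
            if (node, RDF.type, V.IDENTIFIER) in self.graph:
                for s in self.graph.subjects(V.HAS_IDENTIFIER, node):
                    return str(s)
        return None

    def class_iri_by_label(self, label: str) -> Optional[str]:
        for node in self.graph.subjects(RDFS.label, Literal(label)):
            if (node, RDF.type, V.CHEMICAL_CLASS) in self.graph:
                return str(node)
        return None

    def species_in_class(self, class_label: str) -> set[str]:
        """Members of the labeled class, descending the parent hierarchy."""
        rows = self.sparql(
            f"""
            PREFIX os: <{V.OS}>
            PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
            SELECT DISTINCT ?species WHERE {{
              ?cls a os:ChemicalClass ; rdfs:label "{class_label}" .
              ?sub os:hasParentClass* ?cls .
              ?species a os:Species ; os:hasChemicalClass ?sub .
            }}
            """
        )
        return {str(r.species) for r in rows}

    def query_boiling_by_class(
        self, class_label: str
    ) -> list[tuple[int, float, Optional[float]]]:
        """Rows of (carbon count, T_b in K, reference pressure in kPa or None),
        one per boiling-point record of each member of the class."""
        rows = []
        for r in self.sparql(boiling_by_class_query(class_label)):
            formula = parse_formula(str(r.label))
            pref = float(str(r.refPressure)) if r.refPressure is not None else None
            rows.append((formula["C"], float(str(r.value)), pref))
        return sorted(rows, key=lambda t: (t[0], t[1], t[2] is None, t[2] or 0.0))

    def validate(self) -> ValidationReport:
        return validate_shapes(self.graph)
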