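"""Ingestion agent: provider payloads → Species → validated triples.

The agent receives an InChI or SMILES key, checks whether the species is
already instantiated (returning the existing IRI if so), and otherwise
assembles a :class:`~specieskg.model.Species` from two provider documents —
a *computed* record (identifiers plus value+unit properties such as molecular
weight) and an *annotation* record (free-text experimental property strings,
classes, GHS statements, uses, synonyms, spectra).  Property strings run
through the parse → canonicalize → record pipeline; strings without a numeric
value are discarded with a logged reason; a recommended value is selected per
property kind.  Classification hierarchies are imported recursively: the
agent instantiates each missing ancestor exactly once, walking parent links
until reaching classes already present.  The commit is atomic — on provider
failure or shape violation the store is left untouched.

Providers implement a neutral document schema (plain dicts / JSON files), not
any specific provider's wire format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping, Optional, Protocol, Union

from rdflib import Graph, Literal, URIRef

from . import vocab as V
from .curation import select_recommended
from .iri import DEFAULT_NAMESPACE, mint_free_iri, mint_species_iri
from .model import (
    Atom,
    AtomicBond,
    ChemicalClass,
    GHSStatement,
    IdentifierRecord,
    Peak,
    PropertyRecord,
    Provenance,
    Species,
    SpectrumRecord,
    new_uuid,
    parse_formula,
)
from .quantities import records_from_strings, to_canonical, ParsedQuantity
from .shapes import validate_shapes
from .store import SpeciesStore, emit_species_triples
from .vocab import RDF, RDFS

__all__ = [
    "ProviderError",
    "IngestError",
    "ProviderPayload",
    "Provider",
    "InMemoryProvider",
    "FixtureDirectoryProvider",
    "map_computed_payload",
    "map_annotation_payload",
    "import_classification_hierarchy",
    "class_iri_for_source_id",
    "ingest_species",
]

log = logging.getLogger(__name__)


class ProviderError(RuntimeError):
    """A provider could not deliver a document."""


class IngestError(RuntimeError):
    """Ingestion aborted; the store is unchanged."""


@dataclass(frozen=True)
class ProviderPayload:
    source: str  # "computed" | "annotation" | "classification"
    document: Mapping
    provenance: Provenance

    def __post_init__(self) -> None:
        if self.source not in ("computed", "annotation", "classification"):
            raise ValueError(f"unknown payload source {self.source!r}")
        if not self.document:
            raise ValueError("payload document must be non-empty")


class Provider(Protocol):
    """Access to species documents and the classification hierarchy."""

    def computed(self, key: str) -> ProviderPayload: ...

    def annotation(self, key: str) -> ProviderPayload: ...

    def class_info(self, class_id: str) -> dict: ...


@dataclass
class InMemoryProvider:
    """Dict-backed provider, used by the synthetic fixtures and tests."""

    computed_docs: dict[str, dict]
    annotation_docs: dict[str, dict]
    classes: dict[str, dict] = field(default_factory=dict)
    label: str = "fixture provider"

    def computed(self, key: str) -> ProviderPayload:
        if key not in self.computed_docs:
            raise ProviderError(f"no computed record for {key!r}")
        doc = self.computed_docs[key]
        return ProviderPayload(
            "computed", doc,
            Provenance(label=self.label, locator=doc.get("locator")),
        )

    def annotation(self, key: str) -> ProviderPayload:
        if key not in self.annotation_docs:
            raise ProviderError(f"no annotation record for {key!r}")
        doc = self.annotation_docs[key]
        return ProviderPayload(
            "annotation", doc,
            Provenance(label=self.label, locator=doc.get("locator")),
        )

    def class_info(self, class_id: str) -> dict:
        if class_id not in self.classes:
            raise ProviderError(f"unknown class id {class_id!r}")
        return self.classes[class_id]


class FixtureDirectoryProvider:
    """Provider over a directory of JSON documents.

    Layout::

        <dir>/index.json            # {"<key>": "<slug>", ...}
        <dir>/species/<slug>/computed.json
        <dir>/species/<slug>/annotation.json
        <dir>/classes.json          # {"<id>": {"label": ..., "parents": [...]}}
    """

    def __init__(self, directory: Union[str, Path]) -> None:
        self.root = Path(directory)
        self._index = json.loads((self.root / "index.json").read_text())
        classes_path = self.root / "classes.json"
        self._classes = (
            json.loads(classes_path.read_text()) if classes_path.exists() else {}
        )

    def _doc(self, key: str, name: str) -> dict:
        slug = self._index.get(key)
        if slug is None:
            raise ProviderError(f"no fixture for key {key!r}")
        path = self.root / "species" / slug / f"{name}.json"
        if not path.exists():
            raise ProviderError(f"missing {name} document for {key!r}")
        return json.loads(path.read_text())

    def computed(self, key: str) -> ProviderPayload:
        doc = self._doc(key, "computed")
        return ProviderPayload(
            "computed", doc, Provenance(label="fixture directory", locator=doc.get("locator"))
        )

    def annotation(self, key: str) -> ProviderPayload:
        doc = self._doc(key, "annotation")
        return ProviderPayload(
            "annotation", doc, Provenance(label="fixture directory", locator=doc.get("locator"))
        )

    def class_info(self, class_id: str) -> dict:
        if class_id not in self._classes:
            raise ProviderError(f"unknown class id {class_id!r}")
        return self._classes[class_id]


_IDENTIFIER_KEY_MAP = {
    "InChI": "InChI",
    "InChIKey": "InChIKey",
    "IUPACName": "IUPACName",
    "SMILES": "SMILES",
    "CAS": "CAS",
    "MolecularFormula": "MolecularFormulaText",
}


def map_computed_payload(
    payload: ProviderPayload,
) -> tuple[list[IdentifierRecord], list[PropertyRecord]]:
    """Identifiers and value+unit computed properties from a computed record."""
    if payload.source != "computed":
        raise ValueError("payload is not a computed record")
    doc = payload.document
    ident_block = doc.get("identifiers") or {}
    if not ident_block:
        raise IngestError("computed record lacks the identifier block")
    identifiers = [
        IdentifierRecord(kind=_IDENTIFIER_KEY_MAP.get(k, k), value=str(v),
                         provenance=payload.provenance)
        for k, v in sorted(ident_block.items())
        if v
    ]
    properties = []
    indices: dict[str, int] = {}
    for kind, entry in sorted((doc.get("properties") or {}).items()):
        q = ParsedQuantity(value=float(entry["value"]), unit=str(entry["unit"]))
        canonical = to_canonical(q, kind)
        indices[kind] = indices.get(kind, 0) + 1
        properties.append(
            PropertyRecord(
                kind=kind,
                index=indices[kind],
                value=canonical.value,
                unit=canonical.unit,
                provenance=payload.provenance,
            )
        )
    return identifiers, properties


@dataclass(frozen=True)
class AnnotationData:
    raw_property_strings: tuple[tuple[str, str, Provenance], ...]  # (kind, text, prov)
    ghs: tuple[GHSStatement, ...]
    uses: tuple[str, ...]
    synonyms: tuple[str, ...]
    spectra: tuple[SpectrumRecord, ...]
    class_ids: tuple[str, ...]


def map_annotation_payload(payload: ProviderPayload) -> AnnotationData:
    """Verbatim strings (for the parser), hazards, uses, synonyms, spectra."""
    if payload.source != "annotation":
        raise ValueError("payload is not an annotation record")
    doc = payload.document

    raw = []
    for entry in doc.get("experimental_properties", []):
        src = entry.get("source") or {}
        prov = (
            Provenance(label=src.get("label", ""), locator=src.get("locator"))
            if src
            else payload.provenance
        )
        raw.append((str(entry["kind"]), str(entry["string"]), prov))

    ghs = tuple(
        GHSStatement(code=e["code"], text=e.get("text", ""))
        for e in doc.get("ghs", [])
    )
    uses = tuple(str(u) for u in doc.get("uses", []))
    synonyms = tuple(str(s) for s in doc.get("synonyms", []))

    spectra = []
    seq_by_kind: dict[str, int] = {}
    for entry in doc.get("spectra", []):
        kind = entry["kind"]
        seq_by_kind[kind] = seq_by_kind.get(kind, 0) + 1
        peaks = tuple(
            Peak(
                position=float(p["position"]),
                intensity=float(p.get("intensity", 1.0)),
                multiplicity=p.get("multiplicity"),
            )
            for p in entry.get("peaks", [])
        )
        spectra.append(
            SpectrumRecord(
                kind=kind,
                peaks=peaks,
                sequence_number=int(entry.get("sequence_number", seq_by_kind[kind])),
                solvent=entry.get("solvent"),
                frequency=entry.get("frequency"),
                ionization_mode=entry.get("ionization_mode"),
            )
        )
    class_ids = tuple(str(c) for c in doc.get("classes", []))
    return AnnotationData(
        raw_property_strings=tuple(raw),
        ghs=ghs,
        uses=uses,
        synonyms=synonyms,
        spectra=tuple(spectra),
        class_ids=class_ids,
    )


def class_iri_for_source_id(source_id: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Deterministic class-instance IRI from a provider class identifier."""
    safe = "".join(ch if ch.isalnum() else "-" for ch in source_id).strip("-")
    return mint_free_iri("ChemicalClass", safe, namespace)


def import_classification_hierarchy(
    provider: Provider,
    leaf_class_id: str,
    store: SpeciesStore,
    *,
    sink: Optional[Graph] = None,
) -> set[ChemicalClass]:
    """Instantiate the leaf class and every missing ancestor, exactly once.

    Already-present classes (in the store or in ``sink``, when staging an
    atomic ingest) are not duplicated.  Returns the classes newly added.
    Raises :class:`IngestError` on a cyclic hierarchy, naming the cycle.
    """
    target = sink if sink is not None else store.graph

    def present(iri: str) -> bool:
        node = URIRef(iri)
        if (node, RDF.type, V.CHEMICAL_CLASS) in store.graph:
            return True
        return sink is not None and (node, RDF.type, V.CHEMICAL_CLASS) in sink

    added: set[ChemicalClass] = set()
    emitted: set[str] = set()

    def visit(class_id: str, path: tuple[str, ...]) -> None:
        if class_id in path:
            cycle = " -> ".join(path[path.index(class_id):] + (class_id,))
            raise IngestError(f"classification hierarchy contains a cycle: {cycle}")
        iri = class_iri_for_source_id(class_id, store.namespace)
        info = provider.class_info(class_id)
        parent_ids = list(info.get("parents", []))
        if iri not in emitted and not present(iri):
            c = ChemicalClass(
                iri=iri,
                label=str(info["label"]),
                parents=frozenset(
                    class_iri_for_source_id(p, store.namespace) for p in parent_ids
                ),
                source_id=class_id,
            )
            node = URIRef(iri)
            target.add((node, RDF.type, V.CHEMICAL_CLASS))
            target.add((node, RDFS.label, Literal(c.label)))
            target.add((node, V.SOURCE_IDENTIFIER, Literal(class_id)))
            for p in sorted(c.parents):
                target.add((node, V.HAS_PARENT_CLASS, URIRef(p)))
            added.add(c)
            emitted.add(iri)
        for p in parent_ids:
            visit(p, path + (class_id,))

    visit(leaf_class_id, ())
    return added


def _retrying(fn: Callable[[], ProviderPayload], retries: int) -> ProviderPayload:
    last: Optional[Exception] = None
    for _ in range(retries + 1):
        try:
            return fn()
        except ProviderError as exc:
            last = exc
    raise IngestError(f"provider failed after {retries + 1} attempts: {last}") from last


def ingest_species(
    key: str,
    provider: Provider,
    store: SpeciesStore,
    *,
    rel_tol: float = 0.10,
    retries: int = 2,
    uuid_factory: Callable[[], str] = new_uuid,
    clock: Callable[[], datetime] = lambda: datetime.now(timezone.utc),
) -> str:
    """Ingest one species by InChI or SMILES key; returns its IRI.

    Idempotent: a species whose identifier already matches ``key`` is not
    re-instantiated.  Atomic: on any failure the store equals its pre-call
    state.
    """
    if not key:
        raise ValueError("species key must be a non-empty InChI or SMILES string")

    existing = store.find_species_by_identifier(key)
    if existing is not None:
        log.info("species for %r already instantiated as %s", key, existing)
        return existing

    computed = _retrying(lambda: provider.computed(key), retries)
    annotation = _retrying(lambda: provider.annotation(key), retries)

    identifiers, properties = map_computed_payload(computed)
    ann = map_annotation_payload(annotation)

    formula_text = next(
        (i.value for i in identifiers if i.kind == "MolecularFormulaText"), None
    )
    if formula_text is None:
        raise IngestError("computed record lacks a molecular formula")
    formula = parse_formula(formula_text)

    now = clock()
    properties = list(properties)
    strings_by_kind: dict[str, list[tuple[str, Provenance]]] = {}
    for kind, text, prov in ann.raw_property_strings:
        strings_by_kind.setdefault(kind, []).append((text, prov))
    for kind, entries in sorted(strings_by_kind.items()):
        start = 1 + sum(1 for p in properties if p.kind == kind)
        records, discarded = records_from_strings(
            kind, entries, start_index=start, date_acquired=now
        )
        properties.extend(records)
    for kind in sorted({p.kind for p in properties}):
        kind_records = [p for p in properties if p.kind == kind]
        properties.append(select_recommended(kind_records, rel_tol))

    doc = computed.document
    atoms = [
        Atom(index=int(a["index"]), element=str(a["element"]),
             x=a.get("x"), y=a.get("y"), z=a.get("z"))
        for a in doc.get("atoms", [])
    ]
    bonds = [
        AtomicBond(atom_a=int(b["atom_a"]), atom_b=int(b["atom_b"]),
                   order=int(b.get("order", 1)))
        for b in doc.get("bonds", [])
    ]

    # stage everything on a scratch graph so the commit is all-or-nothing
    staged = Graph()
    classes: list[ChemicalClass] = []
    for class_id in ann.class_ids:
        import_classification_hierarchy(provider, class_id, store, sink=staged)
        info = provider.class_info(class_id)
        classes.append(
            ChemicalClass(
                iri=class_iri_for_source_id(class_id, store.namespace),
                label=str(info["label"]),
                parents=frozenset(
                    class_iri_for_source_id(p, store.namespace)
                    for p in info.get("parents", [])
                ),
                source_id=class_id,
            )
        )

    species = Species(
        uuid=uuid_factory(),
        formula=formula,
        alt_labels=frozenset(ann.synonyms),
        atoms=atoms,
        bonds=bonds,
        identifiers=identifiers,
        properties=properties,
        classes=classes,
        ghs_statements=ann.ghs,
        uses=ann.uses,
        spectra=ann.spectra,
    )
    staged += emit_species_triples(species, store.namespace)
    report = validate_shapes(staged)
    if not report.conforms:
        raise IngestError(
            "shape validation failed; ingest aborted: "
            + "; ".join(m for _, _, m in report.violations)
        )
    store.graph += staged
    iri = mint_species_iri(species.uuid, store.namespace)
    log.info("instantiated %s (%d properties, %d classes)",
             iri, len(species.properties), len(species.classes))
    return iri
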