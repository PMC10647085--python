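"""RDF emission, loading, shape validation and query patterns."""

import numpy as np
import pytest
from rdflib import Graph, Literal, URIRef

from specieskg import vocab as V
from specieskg.fixtures import FixtureSpec, gen_random_species, gen_species_library
from specieskg.iri import DEFAULT_NAMESPACE, mint_species_iri
from specieskg.model import (
    ChemicalClass,
    IdentifierRecord,
    PropertyRecord,
    Provenance,
    Species,
    parse_formula,
)
from specieskg.shapes import validate_shapes
from specieskg.store import (
    SpeciesStore,
    StoreError,
    boiling_by_class_query,
    emit_species_triples,
    load_species,
)
from specieskg.vocab import RDF, RDFS, SKOS

PROV = Provenance(label="src", locator="https://example.org/1")


def minimal_species(uuid="u-min", formula="C2H6O", **kwargs):
    defaults = dict(
        identifiers=[IdentifierRecord("InChI", f"InChI=1S/{formula}/{uuid}", PROV)],
    )
    defaults.update(kwargs)
    return Species(uuid=uuid, formula=parse_formula(formula), **defaults)


class TestEmit:
    def test_label_is_formula(self):
        g = emit_species_triples(minimal_species())
        s = URIRef(mint_species_iri("u-min"))
        assert (s, RDFS.label, Literal("C2H6O")) in g

    def test_synonyms_as_alt_labels(self):
        g = emit_species_triples(minimal_species(alt_labels={"ethanol"}))
        s = URIRef(mint_species_iri("u-min"))
        assert (s, SKOS.altLabel, Literal("ethanol")) in g

    def test_minimal_species_valid(self):
        g = emit_species_triples(minimal_species())
        assert validate_shapes(g).conforms


class TestRoundTrip:
    def test_minimal(self):
        sp = minimal_species()
        assert load_species(emit_species_triples(sp), mint_species_iri(sp.uuid)) == sp

    def test_randomized_round_trip_identity(self, rng):
        """emit → load is the identity on 200 randomized full species."""
        for _ in range(200):
            sp = gen_random_species(rng)
            g = emit_species_triples(sp)
            loaded = load_species(g, mint_species_iri(sp.uuid))
            assert loaded == sp

    def test_two_species_loads_isolate(self, rng):
        a, b = gen_random_species(rng), gen_random_species(rng)
        store = SpeciesStore()
        ia, ib = store.add_species(a), store.add_species(b)
        assert store.load_species(ia) == a
        assert store.load_species(ib) == b

    def test_hand_written_turtle_fixture(self, tmp_path):
        ns = DEFAULT_NAMESPACE
        ttl = f"""
        @prefix os: <{V.OS}> .
        @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
        <{ns}Species_h1> a os:Species ; rdfs:label "CH4" ;
            os:hasIdentifier <{ns}SMILES_1_Species_h1> ;
            os:hasProperty <{ns}BoilingPoint_1_Species_h1> .
        <{ns}SMILES_1_Species_h1> a os:Identifier, os:SMILES ;
            os:value "C" ; os:hasProvenance <{ns}Reference_abc> .
        <{ns}BoilingPoint_1_Species_h1> a os:Property, os:BoilingPoint ;
            os:value 111.65 ; os:unit "K" ; os:isRecommended false ;
            os:hasProvenance <{ns}Reference_abc> .
        <{ns}Reference_abc> a os:Reference ; rdfs:label "handwritten" .
        """
        g = Graph()
        g.parse(data=ttl, format="turtle")
        sp = load_species(g, f"{ns}Species_h1")
        assert sp.label == "CH4"
        assert sp.properties[0].value == pytest.approx(111.65)
        assert sp.identifiers[0].kind == "SMILES"

    def test_missing_label_errors(self):
        g = Graph()
        s = URIRef(mint_species_iri("u-x"))
        g.add((s, RDF.type, V.SPECIES))
        with pytest.raises(StoreError):
            load_species(g, str(s))


class TestShapes:
    def test_valid_emissions_conform(self, rng):
        for _ in range(25):
            assert validate_shapes(emit_species_triples(gen_random_species(rng))).conforms

    @pytest.mark.parametrize(
        "victim_predicate,shape",
        [
            (V.UNIT, "PropertyUnitShape"),
            (V.VALUE, "PropertyValueShape"),
            (V.HAS_PROVENANCE, "PropertyProvenanceShape"),
        ],
    )
    def test_mutated_property_node_violates(self, victim_predicate, shape):
        sp = minimal_species(
            properties=[PropertyRecord("BoilingPoint", 1, 351.0, "K", PROV)]
        )
        g = emit_species_triples(sp)
        prop = next(g.subjects(RDF.type, V.PROPERTY))
        g.remove((prop, victim_predicate, None))
        report = validate_shapes(g)
        assert not report.conforms
        assert any(s == shape and str(prop) == focus for focus, s, _ in report.violations)

    def test_mutation_single_mandatory_fields(self, rng):
        """Deleting any one mandatory triple must break conformance."""
        sp = gen_random_species(rng)
        g = emit_species_triples(sp)
        s = URIRef(mint_species_iri(sp.uuid))
        mandatory = [(s, RDFS.label, None)]
        for prop in g.subjects(RDF.type, V.PROPERTY):
            mandatory.append((prop, V.VALUE, None))
        for triple in mandatory:
            mutated = Graph()
            for t in g:
                mutated.add(t)
            mutated.remove(triple)
            assert not validate_shapes(mutated).conforms

    def test_zero_bond_order_violates(self):
        g = emit_species_triples(minimal_species())
        b = URIRef(f"{DEFAULT_NAMESPACE}AtomicBond_1_Species_u-min")
        g.add((b, RDF.type, V.ATOMIC_BOND))
        g.add((b, V.HAS_BOND_ORDER, Literal(0)))
        report = validate_shapes(g)
        assert any(s == "BondOrderShape" for _, s, _ in report.violations)

    def test_recommended_needs_agent_provenance(self):
        sp = minimal_species(
            properties=[PropertyRecord("BoilingPoint", 1, 351.0, "K", PROV)]
        )
        g = emit_species_triples(sp)
        prop = next(g.subjects(RDF.type, V.PROPERTY))
        g.remove((prop, V.IS_RECOMMENDED, None))
        g.add((prop, V.IS_RECOMMENDED, Literal(True)))
        report = validate_shapes(g)
        assert any(s == "RecommendedProvenanceShape" for _, s, _ in report.violations)


class TestQueries:
    @pytest.fixture()
    def populated(self):
        store = SpeciesStore()
        lib = gen_species_library(FixtureSpec(seed=7, n_species=20, untagged_rate=0.0))
        iris = lib.populate(store)
        return store, lib, iris

    def test_class_hierarchy_descent_matches_oracle(self, populated):
        store, lib, iris = populated
        # oracle: reflexive-transitive closure over the known synthetic tree
        truth = lib.ground_truth
        want_hydrocarbons = {
            iri for iri, cls in zip(iris, truth.cls)
            if cls in ("alkane", "alkene")
        }
        assert store.species_in_class("hydrocarbon") == want_hydrocarbons
        want_alcohols = {iri for iri, cls in zip(iris, truth.cls) if cls == "alkanol"}
        assert store.species_in_class("alcohol") == want_alcohols

    def test_boiling_by_class_matches_linear_scan(self, populated):
        store, lib, iris = populated
        rows = store.query_boiling_by_class("alkanol")
        oracle = []
        for iri in iris:
            sp = store.load_species(iri)
            if not any(c.label == "alkanol" for c in sp.classes):
                continue
            for p in sp.properties_of_kind("BoilingPoint"):
                pref = (
                    p.reference_state.value
                    if p.reference_state is not None
                    and p.reference_state.quantity_kind == "pressure"
                    else None
                )
                oracle.append((sp.formula["C"], p.value, pref))
        key = lambda t: (t[0], t[1], t[2] is None, t[2] or 0.0)  # noqa: E731
        assert sorted(rows, key=key) == sorted(oracle, key=key)

    def test_unknown_class_label_empty(self, populated):
        store, _, _ = populated
        assert store.query_boiling_by_class("no such class") == []

    def test_add_class_assertion_idempotent(self, populated):
        store, lib, iris = populated
        cls_iri = store.class_iri_by_label("alkene")
        target = next(i for i in iris if i not in store.species_in_class("alkene"))
        before = len(store.graph)
        store.add_class_assertion(target, cls_iri)
        after_first = len(store.graph)
        store.add_class_assertion(target, cls_iri)
        assert len(store.graph) == after_first == before + 1
        assert target in store.species_in_class("alkene")

    def test_add_class_assertion_unknown_nodes(self, populated):
        store, _, iris = populated
        with pytest.raises(StoreError):
            store.add_class_assertion("http://nope/x", "http://nope/y")

    def test_sparql_basics(self, populated):
        store, _, iris = populated
        rows = list(
            store.sparql(f"PREFIX os: <{V.OS}> SELECT ?s WHERE {{ ?s a os:Species }}")
        )
        assert {str(r.s) for r in rows} == set(iris)
        ask = store.sparql(
            f"PREFIX os: <{V.OS}> ASK {{ <http://nope/x> a os:Species }}"
        )
        assert ask.askAnswer is False

    def test_sparql_syntax_error_surfaces(self, populated):
        store, _, _ = populated
        with pytest.raises(Exception):
            store.sparql("SELECT WHERE {")

    def test_fig_query_equivalence(self, populated):
        """The documented SPARQL text gives the same rows as the helper."""
        store, _, _ = populated
        helper = store.query_boiling_by_class("alkane")
        raw = store.sparql(boiling_by_class_query("alkane"))
        assert len(list(raw)) == len(helper)
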