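"""Ingest provider payloads, validate the graph, and query it with SPARQL.

Shows the knowledge-graph plumbing: species assembled from computed and
annotation payloads become RDF triples under the ABox IRI conventions
(oskg:Species_UUID, oskg:BoilingPoint_1_Species_UUID, ...), every commit is
gated on shape validation, and the embedded store answers SPARQL 1.1 queries
including class-hierarchy descent (alkanols count as alcohols).
"""

from specieskg import FixtureSpec, SpeciesStore, gen_species_library
from specieskg.store import boiling_by_class_query
from specieskg.vocab import OS

store = SpeciesStore()
library = gen_species_library(FixtureSpec(seed=3, n_species=10, untagged_rate=0.0))
iris = library.populate(store)
print(f"ingested {len(iris)} species -> {len(store.graph)} triples")
print("shape validation:", "conforms" if store.validate().conforms else "violations")

rows = store.sparql(
    f"""
    PREFIX os: <{OS}>
    PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
    SELECT ?label (COUNT(?p) AS ?n_properties) WHERE {{
        ?s a os:Species ; rdfs:label ?label ; os:hasProperty ?p .
    }} GROUP BY ?label ORDER BY ?label
    """
)
print("\nproperties per species:")
for r in rows:
    print(f"  {str(r.label):<10} {int(r.n_properties)}")

print("\nalcohol members via hierarchy descent (alkanol ⊑ alcohol):")
for iri in sorted(store.species_in_class("alcohol")):
    print(" ", iri.rsplit("/", 1)[-1])

print("\nboiling points of alcohols (carbon count, T_b/K, P_ref/kPa):")
for row in store.query_boiling_by_class("alcohol")[:5]:
    print(" ", row)
print("(query text available via boiling_by_class_query('alcohol'))")
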