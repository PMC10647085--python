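"""Audit classification tags against structural rules.

An alkene is a species with formula CxH2x carrying exactly one double bond.
The synthetic library deliberately leaves a fraction of species untagged;
the audit finds them (so the tag can be added with a SPARQL update via
``add_class_assertion``) and verifies that no tagged species violates the
rule.  A hand-made wrongly tagged alkadiene (C20H38 with two double bonds)
is then planted to show violation reporting.
"""

from specieskg import FixtureSpec, SpeciesStore, gen_species_library
from specieskg.analysis import (
    check_class_consistency,
    find_missing_class_tags,
    load_class_rules,
)
from specieskg.ingest import ingest_species

store = SpeciesStore()
library = gen_species_library(FixtureSpec(seed=7, n_species=40, untagged_rate=0.4))
library.populate(store)
rule = load_class_rules()["alkene"]

missing = find_missing_class_tags(store, rule)
truth = library.ground_truth
expected = int(((truth.cls == "alkene") & ~truth.tagged).sum())
print(f"species matching the alkene rule but untagged: {len(missing)} "
      f"(generator planted {expected})")

print("tagged species violating the rule:", check_class_consistency(store, rule))

# plant a wrongly tagged alkadiene and re-run the consistency check
provider = library.provider
key = "InChI=1S/C20H38/planted"
provider.computed_docs[key] = {
    "identifiers": {"InChI": key, "MolecularFormula": "C20H38"},
    "bonds": [
        {"atom_a": i, "atom_b": i + 1, "order": 2 if i in (1, 5) else 1}
        for i in range(1, 20)
    ],
    "atoms": [{"index": i + 1, "element": "C"} for i in range(20)],
}
provider.annotation_docs[key] = {"classes": ["cls:alkene"]}
ingest_species(key, provider, store)

for iri, reason in check_class_consistency(store, rule):
    print(f"violation: {iri}\n  {reason}")
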