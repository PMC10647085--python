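# specieskg

A chemical-species knowledge-graph toolkit for cheminformatics data
curation.  Public chemical databases report the *same* physical property as
free-text strings in wildly different dialects — `134.4 °F at 760 mmHg
(NTP, 1992)`, `56.7 °C`, `1,000,000 mg/L (at 25 °C)` — and occasionally with
outright errors.  `specieskg` turns such heterogeneous records into a typed,
provenance-tracked RDF knowledge graph and runs the analyses such a graph
makes cheap: recommended-value curation with discrepancy detection,
¹H-NMR-based mixture identification, multi-criteria co-solvent selection,
homologous-series trend extrapolation and classification auditing.

It is aimed at researchers building or consuming chemical knowledge graphs
who need the whole pipeline to be inspectable and reproducible offline: every
step is a plain Python function, every value in the graph keeps its original
string and source, and a synthetic-fixtures module generates provider
payloads with known ground truth so the full stack is testable without any
network access.

## What it computes

**Data model and RDF emission.** A `Species` aggregates formula (Hill
notation is the canonical label), atoms/bonds, identifiers (InChI, SMILES,
CAS…), property records, classification-hierarchy memberships, GHS hazard
statements, uses and spectra.  `emit_species_triples` materializes it under
the ABox IRI conventions `oskg:Species_UUID` and
`oskg:BoilingPoint_#index#_Species_UUID`; `load_species` is its exact
inverse, and every commit to the embedded store is gated on shape validation
(label present, properties carry value/unit/provenance, bond orders are
positive integers, …).

**Quantity parsing.** `parse_property_string` extracts numeric quantities
with units, keeps measurement conditions (`at 25 °C`, `@ 760 mmHg`) separate
from the measured value, records inequality/approximation qualifiers, and
discards strings without a numeric value.  `to_canonical` converts exactly
to canonical units: temperature → K, pressure → kPa (760 mmHg = 101.325
kPa), mass concentration → kg/m³, molar mass → g/mol.

**Curation.** With several records of one property, `select_recommended`
groups approximately equal values by single-linkage on relative distance
(default tolerance 10%), takes the largest group and picks a representative
(metric originals preferred, then most decimal places, then lowest index);
the result is a new record flagged `isRecommended` with the curation agent's
provenance.  `flag_discrepant` reports records deviating from it by more
than 20%.

**Analysis agents.** Mixture identification prunes library peaks below 20%
of each species' strongest peak and keeps species whose every retained peak
lies within ±0.2 ppm of an observed analyte peak, then refines by
multiplicity; co-solvent selection requires |ΔT_b| ≥ 15 K and no
H350*/H360* hazard codes; trend fitting solves T_b(n) = a·n^(1/3) + b by
least squares; audits compare class tags against structural rules
(e.g. alkene ⇔ formula CₓH₂ₓ with exactly one double bond).

## Worked example

`python examples/01_curate_boiling_points.py` curates the five boiling-point
strings PubChem lists for methyl acetate:

```
index  kelvin      original string
    1  330.03889   134.4 °F at 760 mmHg (NTP, 1992)
    2  329.85000   56.7 °C
    3  808.85000   535.70 °C @ 760.00 mmHg (est)
    4  330.15000   57 °C
    5  330.37222   135 °F

recommended value: 329.85 K (provenance: 'PubChem agent')
discrepant: 808.85 K (145% off) from '535.70 °C @ 760.00 mmHg (est)'
```

Four sources agree near 330 K; the curation stage selects the metric,
one-decimal `56.7 °C` entry as the recommended value and flags the 808.85 K
record — a likely typo at source — as discrepant.  The other example
scripts (`examples/02`–`05`) demonstrate NMR mixture identification,
cube-root trend extrapolation, classification auditing, and the
ingest → validate → SPARQL workflow; each prints the numbers it computes
with a line on what they mean.

A thin CLI wraps the same functions:

```
specieskg gen-fixtures --seed 1 --out fixtures/
specieskg ingest --inchi "<key>" --fixtures fixtures/ --store graph.ttl
specieskg validate graph.ttl
specieskg identify-nmr --peaks peaks.tsv --store graph.ttl
specieskg fit-trend --class alkane --store graph.ttl --extrapolate 12:20
specieskg audit --rule alkene --store graph.ttl
```

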