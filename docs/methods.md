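# Methods

This note documents the models, policies and numerical choices behind
`specieskg`, the assumptions they rest on, and what the synthetic fixtures
do and do not show about real data.

## Data model and IRI conventions

A species is an aggregate of structure (atoms with optional Å coordinates,
unordered bonds with integer order), identifiers, provenance-tracked
property records, classification memberships, GHS statements, uses and
spectra.  Invariants are enforced at construction: atom indices unique,
property indices per kind consecutive from 1, the species label equal to
the Hill rendering of its formula (C first, then H, then other elements
alphabetically; carbon-free formulas fully alphabetical).

Instance IRIs are deterministic: `oskg:Species_UUID` for species,
`oskg:<ClassTypeName>_<index>_Species_UUID` (index 1-based) for instances
attached to a species, and `oskg:<ClassTypeName>_<id>` for free-standing
concepts.  Shared nodes that carry no natural identifier — provenances and
uses — are minted from a 12-hex-digit SHA-1 of their content, which
deduplicates them across species and keeps emission deterministic.  The
namespace defaults to `http://www.theworldavatar.com/kg/ontospecies/` and is
configurable per store.

UUIDs are random 128-bit values; the generator accepts a seeded
`numpy.random.Generator` so fixtures and tests are reproducible.

Numeric literals are emitted as `xsd:decimal` via the float's shortest
`repr`, which makes emit → load lossless for doubles; dates are
`xsd:dateTime`.

## Quantity parsing

The parser normalizes, in order: qualifier phrases ("Greater than or equal
to" → `at_least`, "(est)"/"~" → `approx`), parentheticals (condition-bearing
ones like `(at 25 °C)` are inlined, citations like `(NTP, 1992)` dropped —
the discriminator is whether the content contains a number-with-unit),
thousands separators, and spelled scientific notation (`1 × 10 + 6` →
`1e+6`).  Quantities are then `number + unit-alias` matches; a quantity
immediately preceded by "at" or "@" is always a measurement condition, never
a value (the only workable disambiguation when value and condition share a
dimension).  All conditions found in a string attach to every value it
yields.  Bare numbers without a recognizable unit and comma-decimal locales
are discarded with a logged reason, as are strings with no numeric value at
all — qualitative solubility classes ("miscible", "soluble") are
deliberately not mapped to ordinal scales.

Unit spellings map to a closed canonical set through a shipped text config
(`data/unit_aliases.toml`, extensible at run time).  Conversions are exact:
K/°C/°F by the defining affine formulas; pressure multiplicatively with
1 atm = 760 mmHg = 101.325 kPa.  Canonical units are K (temperature), kPa
(pressure — chosen over Pa because downstream boiling-point queries report
kPa), kg/m³ (mass concentration and density), g/mol (molar mass).
Canonicalization is idempotent and raises on dimension mismatch (a length
offered as a boiling point), which discards the record with a reason.

A record's reference state is derived from its parsed conditions:
temperature-valued properties take their pressure condition (a boiling point
is conditioned on pressure); all other kinds prefer the temperature
condition.  Only one reference state is stored per record.

## Recommended-value selection and discrepancy detection

Grouping is single linkage on relative distance |v_i − v_j| / min(v_i, v_j)
≤ `rel_tol`, computed by union-find over all pairs; groups form a partition
and the result is deterministic in input order.  The default `rel_tol` =
0.10 tolerates unit-conversion and rounding scatter between sources while
separating genuinely different values.

Selection policy (a deterministic policy had to be declared; the following
is minimal and fully ordered): largest group wins, ties broken by group
median closest to the global median, then lowest member index; within the
winning group prefer records whose original string used a metric unit
(non-metric spellings: °F, mmHg, atm), then the original numeric token with
the most decimal places (a proxy for reported precision), then the lowest
index.  The recommended value is a *selected member*, never an average —
averaging would manufacture a value no source reported.  It is stored as a
new record (index continuing after the inputs) with `isRecommended = true`,
provenance label exactly `"PubChem agent"`, and no original string or
reference state (it summarizes a group possibly spanning states).

Discrepancy flags records with |v − v_rec| / v_rec strictly greater than
0.20 ("exceeding 20%"); the recommended record itself is never flagged, and
the check is scale-invariant by construction.

## Knowledge-graph store and validation

The store is an in-memory rdflib graph; SPARQL 1.1 queries run against it
directly.  Class hierarchies are asserted between class *individuals* with a
dedicated parent predicate and queries descend it with a `hasParentClass*`
property path, so members of subclasses count as members of the parent
(alkanols are alcohols).  Classification import is recursive: the leaf and
every missing ancestor are instantiated exactly once (DFS with cycle
detection; class IRIs derive deterministically from provider identifiers, so
re-imports are no-ops).

Shape validation gates every commit: species have exactly one label and at
least one identifier; property nodes carry a decimal value, a unit and a
provenance; recommended nodes carry the curation agent's provenance label;
bond orders are positive integers; peaks have positions.  The validator is
implemented natively over rdflib and returns (focus node, shape, message)
violations; an equivalent SHACL document ships as `data/shapes.ttl` for
external SHACL processors.

Ingestion is atomic by staging: provider documents are fetched first (with
bounded retries), all triples including the class hierarchy are built on a
scratch graph, validated, and only then merged — any failure leaves the
store bit-identical.  Duplicate detection keys on exact identifier string
match (InChI when the key looks like one, else SMILES).  Acquisition dates
come from an injectable clock.

## Analysis agents

**NMR identification.**  Candidates are species with C/H/O-only formulas
(C and H required, O optional), C < 5 and O < 10, and a recommended boiling
point above 288.15 K (liquid at room temperature with margin below the
25 °C experiment).  Library peaks below 20% of the species' strongest peak
are pruned first.  Stage 1 requires *all* retained peaks of a species to lie
within ±0.2 ppm of some observed analyte peak — a species present in the
mixture must exhibit all its major peaks; requiring only one match would
admit any species with one lucky peak.  Reference and solvent peaks (DMSO
at 2.6 ppm, water at 4.9 ppm in the bundled example) are excluded via
explicit peak roles rather than hard-coded shift constants.  Stage 2 keeps
candidates whose matched multiplicities agree (unknown library
multiplicities pass) and that place at most one library peak in any observed
window — two peaks crowding one observed singlet contradict the observed
pattern.  Chemical-plausibility reasoning beyond the spectrum (e.g.
preferring ethanol over ethoxyethane among surviving candidates) is out of
scope, as is shift prediction from structure.

**Co-solvent selection.**  |T_b − T_b,ref| ≥ 15 K (ease of separation by
distillation; the bound is inclusive and symmetric), exclusion of GHS codes
with prefixes H350 (carcinogenicity) and H360 (reproductive toxicity), and
an optional boiling-point ceiling (solvent-recovery cost).  Only recommended
boiling points are used; species lacking one are excluded rather than
guessed.

**Trends.**  T_b(n) = a·n^(1/3) + b is linear in the (n^(1/3), 1) basis and
solved in closed form by `numpy.linalg.lstsq`; the fit object carries the
residual sum of squares and point count.  Extrapolation simply evaluates
the model.

**Audits.**  Structural rules pair a formula pattern with an optional exact
double-bond count (shipped registry: alkane CₙH₂ₙ₊₂; alkene CₙH₂ₙ with one
double bond; alkanol CₙH₂ₙ₊₂O).  Patterns require the exact element set, so
an oxygen-containing formula never matches the alkene pattern.  Double
bonds are counted over stored bonds; a species without bond data counts
zero.  Acyclicity is not additionally required for alkene detection — the
rule is formula plus one double bond, as stated.

## Synthetic fixtures

Generators emulate provider payloads in a neutral JSON schema, not any
provider's wire format.  One pseudo-random stream per artifact, keyed by
(seed, purpose tag), guarantees that adding a generator never shifts
existing fixtures; a seed fully determines output.

Property strings render a true value in mixed dialects (K / °C / °F-with-
condition / °C-@-pressure; mg/L-with-condition / spelled scientific
notation / mg/mL), with rounding kept within 0.5% of the truth; with
probability `outlier_rate` (default 0.1) a string renders ×2–×3 the truth
and is recorded as a planted outlier.  The species library (default 30
species) draws classes uniformly from alkane/alkene/alkanol with 1–12
carbons, boiling points on class trends a·n^(1/3)+b — (170, −60), (172,
−58), (175, 45) K respectively, magnitudes resembling light-hydrocarbon
series — plus σ = 2 K Gaussian noise, 2–5 strings per value, NMR spectra on
75% of species (1–4 peaks, 0.5–10 ppm, occasionally a deliberately minor
peak for the pruning step), GHS codes on 25%, and a 20% untagged fraction
so audits have known answers.  Mixture spectra take the union of planted
species' retained peaks jittered within ±0.1 ppm (half the matching
window), plus the reference and solvent peaks.

What passing these tests shows: the pipeline's logic — parsing dialects,
grouping, selection, flagging, matching, fitting, auditing — is correct
against independent oracles and planted ground truth.  What it does not
show: robustness to the full zoo of real provider strings (only the encoded
dialects are covered), real NMR shift distributions and overlapping
multiplets, or curation behaviour when outliers form the majority of
sources (the majority-group policy is then undefined by design).

## Problem sizes and numerical notes

Default test sizes — 200 randomized species for round-trip/validation
properties, libraries of 10–40 species for store-level tests, 100 seeded
trials for planted-recovery and outlier-flagging properties, DAGs of ≤ 50
nodes for hierarchy import — were chosen so the whole suite runs in seconds
on one CPU while exercising every code path; all scale linearly if
enlarged.  Temperature conversions are exact to float precision (the °F↔K↔°C
round trip holds to 1e-9 relative); the displayed 5-decimal kelvin values in
the curation walk-through agree with the computed ones to < 1e-5 (display
truncation versus rounding in the last digit).  Ties throughout (grouping
order, selection, matching assignment) are broken deterministically as
documented above, so all results are order-independent except where a
genuine tie is resolved by input index.

## Known limitations

- No live HTTP providers: data enters through the in-memory or
  fixture-directory provider implementations.  The provider protocol is
  three methods; a network-backed implementation can be dropped in.
- No remote SPARQL endpoint; the store is embedded and in-memory, with
  Turtle read/write for persistence.
- Identifiers are stored, never derived: no InChI computation from
  structure, no stereochemistry or aromaticity perception.
- The recommended-value policy is a declared convention; other reasonable
  policies (source ranking, uncertainty weighting) would pick differently
  in edge cases and are intentionally not implemented.
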