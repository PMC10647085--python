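"""Curate heterogeneous boiling-point strings into a recommended value.

The five source strings below are the boiling points PubChem lists for
methyl acetate, in a mix of °F/°C dialects with measurement conditions and
citations.  The pipeline parses each string, converts to kelvin, selects a
recommended value (largest group of approximately equal values, metric and
most-precise original preferred) and flags records deviating from it by more
than 20% — here a far-off estimate most likely caused by a typo at source.
"""

from specieskg import (
    METHYL_ACETATE_BOILING_STRINGS,
    Provenance,
    flag_discrepant,
    records_from_strings,
    select_recommended,
)

provenance = Provenance(label="PubChem annotation")
records, discarded = records_from_strings(
    "BoilingPoint", [(s, provenance) for s in METHYL_ACETATE_BOILING_STRINGS]
)

print("index  kelvin      original string")
for r in records:
    print(f"{r.index:>5}  {r.value:<10.5f}  {r.original_string}")

recommended = select_recommended(records)
print(f"\nrecommended value: {recommended.value:.2f} K "
      f"(provenance: {recommended.provenance.label!r})")

for r in flag_discrepant(records, recommended):
    deviation = abs(r.value - recommended.value) / recommended.value
    print(f"discrepant: {r.value:.2f} K ({deviation:.0%} off) "
          f"from {r.original_string!r}")
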