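"""Identify mixture components from a ¹H-NMR spectrum by peak matching.

The observed spectrum is the six-peak catholyte sample of a CO₂
electroreduction experiment: the 2.6 ppm peak is the DMSO internal standard
(reference role) and 4.9 ppm is water (solvent role); neither opens a
matching window.  The library holds candidate species' recorded peaks plus
three decoys.  Stage 1 keeps species all of whose major peaks (≥ 20% of the
strongest) fall within ±0.2 ppm of an observed analyte peak; stage 2 checks
multiplicities and rejects candidates crowding two peaks into one window.
"""

from specieskg import mixture_demo_library, catholyte_observed_peaks
from specieskg.analysis import (
    identify_mixture,
    match_species_to_spectrum,
    prune_minor_peaks,
)

library = mixture_demo_library()
observed = catholyte_observed_peaks()

print("observed peaks (ppm, multiplicity, role):")
for p in observed:
    print(f"  {p.shift:>5.2f}  {p.multiplicity:<8}  {p.role}")

pruned = {name: prune_minor_peaks(peaks) for name, peaks in library.items()}
stage1 = [m.species_iri for m in match_species_to_spectrum(pruned, observed)]
print("\nstage-1 candidates (all major peaks inside a window):", sorted(stage1))

final = identify_mixture(library, observed)
print("after multiplicity refinement:", sorted(final))
print("\nEach named species is consistent with the spectrum; the decoys were"
      "\nrejected (peak outside every window / wrong multiplicity / two peaks"
      "\nin one window).")
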