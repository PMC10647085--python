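"""Fit a homologous-series boiling-point trend and extrapolate it.

Generates a synthetic species library whose alkane boiling points follow
T_b(n) = a·n^(1/3) + b plus noise, ingests it into an in-memory knowledge
graph, queries the recommended boiling points of the class members via the
hierarchy-descending class query, fits the cube-root trend by least squares
and extrapolates to longer chains.
"""

from specieskg import FixtureSpec, SpeciesStore, gen_species_library
from specieskg.analysis import extrapolate_bp, fit_cube_root, trend_points
from specieskg.fixtures import TREND_COEFFICIENTS

store = SpeciesStore()
library = gen_species_library(FixtureSpec(seed=42, n_species=40, untagged_rate=0.0))
library.populate(store)

points = sorted(trend_points(store, "alkane"))
print(f"{len(points)} alkane (carbon count, T_b/K) points, e.g. {points[:3]}")

fit = fit_cube_root(points)
a_true, b_true = TREND_COEFFICIENTS["alkane"]
print(f"fitted   a = {fit.a:7.2f} K, b = {fit.b:7.2f} K "
      f"(generator truth: a = {a_true}, b = {b_true})")
print(f"residual sum of squares: {fit.residual_ss:.1f} K² over {fit.n_points} points")

print("\nextrapolated boiling points:")
for n in (14, 16, 18, 20):
    print(f"  n = {n:>2}: {extrapolate_bp(fit, n):6.1f} K")
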