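"""Query-plus-computation agents over a species store.

Four use cases:

* **NMR mixture identification** — candidate species are pre-filtered by
  formula (C/H/O only, bounded carbon and oxygen counts) and boiling point
  (liquid at room temperature), their recorded ¹H-NMR peaks are pruned of
  minor signals (< 20% of the strongest peak), and a two-stage matcher keeps
  species all of whose retained peaks fall within ±0.2 ppm of an observed
  analyte peak (stage 1) and whose multiplicities agree, with at most one
  library peak per observed window (stage 2).  Reference (DMSO) and solvent
  (water) peaks are excluded from matching via peak roles.
* **Co-solvent selection** — class members whose boiling point differs from
  the reference solvent's by at least 15 K (ease of separation by
  distillation), excluding GHS carcinogenicity/reproductive-toxicity codes,
  optionally capped at a maximum boiling point (solvent-recovery cost).
* **Homologous-series trends** — least-squares fit of T_b(n) = a·n^(1/3) + b
  against carbon count, used to extrapolate missing boiling points.
* **Classification auditing** — find species that satisfy a structural rule
  (formula pattern, optionally an exact double-bond count) but miss the class
  tag, and tagged species that violate the rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdflib import URIRef

from . import vocab as V
from .model import (
    EmpiricalFormula,
    Peak,
    count_double_bonds,
    formula_matches,
    parse_formula,
)
from .store import SpeciesStore
from .vocab import RDF, RDFS

__all__ = [
    "ObservedPeak",
    "MatchResult",
    "TrendFit",
    "ClassRule",
    "load_class_rules",
    "recommended_value",
    "filter_nmr_candidates",
    "first_nmr_peaks",
    "prune_minor_peaks",
    "match_species_to_spectrum",
    "refine_by_multiplicity",
    "identify_mixture",
    "select_cosolvents",
    "fit_cube_root",
    "extrapolate_bp",
    "find_missing_class_tags",
    "check_class_consistency",
]

PEAK_ROLES = ("analyte", "reference", "solvent")


@dataclass(frozen=True)
class ObservedPeak:
    shift: float
    multiplicity: Optional[str] = None
    role: str = "analyte"

    def __post_init__(self) -> None:
        if self.role not in PEAK_ROLES:
            raise ValueError(f"unknown peak role {self.role!r}")


@dataclass(frozen=True)
class MatchResult:
    species_iri: str
    matched_pairs: tuple[tuple[ObservedPeak, Peak], ...]
    unmatched_library_peaks: tuple[Peak, ...] = ()


@dataclass(frozen=True)
class TrendFit:
    """T_b(n) = a·n^(1/3) + b, fitted by linear least squares."""

    a: float
    b: float
    residual_ss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a trend fit needs at least two points")
        if self.residual_ss < 0:
            raise ValueError("residual sum of squares cannot be negative")


# ----------------------------------------------------------------------------
# store access helpers


def recommended_value(
    store: SpeciesStore, species_iri: str, kind: str
) -> Optional[float]:
    """The recommended (curated) value of a property kind, if any."""
    rows = store.sparql(
        f"""
        PREFIX os: <{V.OS}>
        SELECT ?value WHERE {{
          <{species_iri}> os:hasProperty ?p .
          ?p a os:{kind} ; os:isRecommended true ; os:value ?value .
        }}
        """
    )
    for r in rows:
        return float(str(r.value))
    return None


def _species_formula(store: SpeciesStore, species_iri: str) -> EmpiricalFormula:
    label = store.graph.value(URIRef(species_iri), RDFS.label)
    return parse_formula(str(label))


def first_nmr_peaks(store: SpeciesStore, species_iri: str) -> Optional[list[Peak]]:
    """Peaks of the species' first recorded 1-D ¹H-NMR spectrum (lowest
    sequence number), or None when the species has no such spectrum."""
    species = store.load_species(species_iri)
    nmr = [s for s in species.spectra if s.kind == "NMR1D"]
    if not nmr:
        return None
    first = min(nmr, key=lambda s: s.sequence_number)
    return list(first.peaks)


# ----------------------------------------------------------------------------
# NMR mixture identification


def filter_nmr_candidates(
    store: SpeciesStore,
    c_max: int = 5,
    o_max: int = 10,
    tb_min_K: float = 288.15,
) -> list[str]:
    """Species that could plausibly sit in a room-temperature liquid sample:
    C/H/O-only formula with C < c_max and O < o_max, and a recommended boiling
    point above ``tb_min_K``.  Species without a boiling point are excluded."""
    out = []
    for iri in store.species_iris():
        formula = _species_formula(store, iri)
        if not formula_matches(formula, "bounded_CHO", x_max=c_max, z_max=o_max):
            continue
        tb = recommended_value(store, iri, "BoilingPoint")
        if tb is None or tb <= tb_min_K:
            continue
        out.append(iri)
    return out


def prune_minor_peaks(peaks: Sequence[Peak], rel_threshold: float = 0.20) -> list[Peak]:
    """Keep peaks whose intensity is at least ``rel_threshold`` of the
    strongest peak."""
    if not peaks:
        raise ValueError("cannot prune an empty peak list")
    top = max(p.intensity for p in peaks)
    return [p for p in peaks if p.intensity >= rel_threshold * top]


def match_species_to_spectrum(
    library: Mapping[str, Sequence[Peak]],
    observed: Sequence[ObservedPeak],
    window: float = 0.2,
) -> list[MatchResult]:
    """Stage 1: species all of whose library peaks are covered by a window.

    Only observed peaks with the ``analyte`` role open matching windows;
    reference and solvent peaks are excluded.  Each library peak is assigned
    to the nearest covering observed peak.  Species with any uncovered
    library peak are rejected (not returned).
    """
    analyte = [p for p in observed if p.role == "analyte"]
    results = []
    for species_iri in sorted(library):
        peaks = library[species_iri]
        pairs = []
        covered = True
        for lp in peaks:
            in_window = [op for op in analyte if abs(op.shift - lp.position) <= window]
            if not in_window:
                covered = False
                break
            nearest = min(in_window, key=lambda op: abs(op.shift - lp.position))
            pairs.append((nearest, lp))
        if covered and peaks:
            results.append(MatchResult(species_iri, tuple(pairs)))
    return results


def refine_by_multiplicity(
    candidates: Sequence[MatchResult],
    observed: Sequence[ObservedPeak],
    window: float = 0.2,
) -> list[str]:
    """Stage 2: keep candidates whose matched multiplicities agree and that
    place at most one library peak inside any observed analyte window.

    Library peaks with unknown multiplicity pass the multiplicity test."""
    analyte = [p for p in observed if p.role == "analyte"]
    survivors = []
    for cand in candidates:
        ok = all(
            lp.multiplicity is None or lp.multiplicity == op.multiplicity
            for op, lp in cand.matched_pairs
        )
        if ok:
            lib_peaks = [lp for _, lp in cand.matched_pairs]
            for op in analyte:
                n_in_window = sum(
                    1 for lp in lib_peaks if abs(op.shift - lp.position) <= window
                )
                if n_in_window > 1:
                    ok = False
                    break
        if ok:
            survivors.append(cand.species_iri)
    return survivors


def identify_mixture(
    library: Mapping[str, Sequence[Peak]],
    observed: Sequence[ObservedPeak],
    window: float = 0.2,
    prune_threshold: float = 0.20,
) -> list[str]:
    """Full two-stage identification over a peak library (pruning included)."""
    pruned = {iri: prune_minor_peaks(peaks, prune_threshold)
              for iri, peaks in library.items() if peaks}
    stage1 = match_species_to_spectrum(pruned, observed, window)
    return refine_by_multiplicity(stage1, observed, window)


# ----------------------------------------------------------------------------
# co-solvent selection


def select_cosolvents(
    store: SpeciesStore,
    ref_species: str,
    class_label: str,
    delta_tb_min_K: float = 15.0,
    excluded_hazard_prefixes: Iterable[str] = ("H350", "H360"),
    tb_max_K: Optional[float] = None,
) -> list[str]:
    """Candidate co-solvents for ``ref_species`` among members of a class.

    Criteria: boiling point at least ``delta_tb_min_K`` away from the
    reference's (separability by distillation); no GHS hazard code starting
    with an excluded prefix (by default carcinogenicity H350* and
    reproductive toxicity H360*); optionally a boiling-point ceiling.
    """
    tb_ref = recommended_value(store, ref_species, "BoilingPoint")
    if tb_ref is None:
        raise ValueError(f"reference species {ref_species} lacks a recommended boiling point")
    prefixes = tuple(excluded_hazard_prefixes)
    selected = []
    for iri in sorted(store.species_in_class(class_label)):
        if iri == ref_species:
            continue
        tb = recommended_value(store, iri, "BoilingPoint")
        if tb is None or abs(tb - tb_ref) < delta_tb_min_K:
            continue
        if tb_max_K is not None and tb >= tb_max_K:
            continue
        species = store.load_species(iri)
        if any(g.code.startswith(prefixes) for g in species.ghs_statements):
            continue
        selected.append(iri)
    return selected


# ----------------------------------------------------------------------------
# homologous-series trends


def fit_cube_root(points: Sequence[tuple[float, float]]) -> TrendFit:
    """Least-squares fit of T_b = a·n^(1/3) + b over (carbon count, T_b).

    Linear in the (n^(1/3), 1) basis; solved in closed form via the normal
    equations (numpy lstsq).
    """
    if len({n for n, _ in points}) < 2:
        raise ValueError("need at least two distinct carbon counts")
    n = np.asarray([p[0] for p in points], dtype=float)
    tb = np.asarray([p[1] for p in points], dtype=float)
    design = np.column_stack([np.cbrt(n), np.ones_like(n)])
    coef, *_ = np.linalg.lstsq(design, tb, rcond=None)
    residuals = tb - design @ coef
    return TrendFit(
        a=float(coef[0]),
        b=float(coef[1]),
        residual_ss=float(residuals @ residuals),
        n_points=len(points),
    )


def extrapolate_bp(fit: TrendFit, n: int) -> float:
    """Predicted boiling point at carbon count ``n`` (kelvin)."""
    if n < 1:
        raise ValueError("carbon count must be at least 1")
    return fit.a * float(n) ** (1.0 / 3.0) + fit.b


def trend_points(store: SpeciesStore, class_label: str) -> list[tuple[int, float]]:
    """(carbon count, recommended T_b) for each member of a class."""
    points = []
    for iri in sorted(store.species_in_class(class_label)):
        tb = recommended_value(store, iri, "BoilingPoint")
        if tb is None:
            continue
        points.append((_species_formula(store, iri)["C"], tb))
    return points


# ----------------------------------------------------------------------------
# classification auditing


@dataclass(frozen=True)
class ClassRule:
    """Structural membership rule for a chemical class."""

    class_label: str
    formula_pattern: str
    double_bond_count: Optional[int] = None


def load_class_rules(path: Optional[str] = None) -> dict[str, ClassRule]:
    """Rule registry mapping class labels to structural rules.

    Ships with alkane / alkene / alkanol; a JSON file with the same schema
    may extend or override it.
    """
    raw = resources.files("specieskg").joinpath("data/class_rules.json").read_text()
    table = json.loads(raw)
    if path is not None:
        table.update(json.loads(open(path).read()))
    return {
        label: ClassRule(
            class_label=label,
            formula_pattern=entry["formula_pattern"],
            double_bond_count=entry.get("double_bond_count"),
        )
        for label, entry in table.items()
    }


def _satisfies_rule(store: SpeciesStore, species_iri: str, rule: ClassRule) -> bool:
    formula = _species_formula(store, species_iri)
    if not formula_matches(formula, rule.formula_pattern):
        return False
    if rule.double_bond_count is not None:
        species = store.load_species(species_iri)
        if count_double_bonds(species.bonds) != rule.double_bond_count:
            return False
    return True


def find_missing_class_tags(store: SpeciesStore, rule: ClassRule) -> list[str]:
    """Species satisfying the structural rule but missing the class tag."""
    tagged = store.species_in_class(rule.class_label)
    return [
        iri
        for iri in store.species_iris()
        if iri not in tagged and _satisfies_rule(store, iri, rule)
    ]


def check_class_consistency(
    store: SpeciesStore, rule: ClassRule
) -> list[tuple[str, str]]:
    """Tagged species that violate the structural rule, with a reason."""
    violations = []
    for iri in sorted(store.species_in_class(rule.class_label)):
        if _satisfies_rule(store, iri, rule):
            continue
        formula = _species_formula(store, iri)
        reason = (
            f"tagged {rule.class_label!r} but formula {formula} "
            f"fails pattern {rule.formula_pattern!r}"
        )
        if rule.double_bond_count is not None and formula_matches(
            formula, rule.formula_pattern
        ):
            species = store.load_species(iri)
            reason = (
                f"tagged {rule.class_label!r} but has "
                f"{count_double_bonds(species.bonds)} double bonds, "
                f"expected {rule.double_bond_count}"
            )
        violations.append((iri, reason))
    return violations
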