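"""Synthetic provider payloads, species libraries and mixture spectra.

Everything needed to exercise the toolkit without network access: property
strings rendered in mixed unit dialects with planted far-off outliers,
classification trees, species libraries whose boiling points follow a
cube-root trend in carbon count, ¹H-NMR peak libraries, and mixture spectra
with known planted ground truth.  All randomness is drawn from one stream
per artifact, keyed by ``(seed, purpose tag)``, so adding a generator never
shifts existing fixtures.  Fixtures are statistically — not chemically —
realistic: shifts, intensities and trend coefficients have plausible
magnitudes but do not reproduce real compounds.

The module also carries small curated reference inputs used in examples and
tests: the five boiling-point strings PubChem lists for methyl acetate, the
nine solubility strings PubChem lists for ethanol, and the six-peak ¹H-NMR
spectrum of a CO₂-electroreduction catholyte sample (DMSO internal standard
at 2.6 ppm, water solvent at 4.9 ppm).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import ObservedPeak
from .elements import ATOMIC_MASS
from .ingest import InMemoryProvider, ingest_species
from .model import EmpiricalFormula, Peak
from .store import SpeciesStore

__all__ = [
    "METHYL_ACETATE_BOILING_STRINGS",
    "ETHANOL_SOLUBILITY_STRINGS",
    "catholyte_observed_peaks",
    "mixture_demo_library",
    "FixtureSpec",
    "GeneratedPropertyString",
    "gen_property_strings",
    "SyntheticLibrary",
    "gen_species_library",
    "gen_mixture_spectrum",
    "gen_class_dag",
    "SYNTHETIC_CLASS_TREE",
    "TREND_COEFFICIENTS",
]

#: The five boiling-point strings listed by PubChem for methyl acetate,
#: verbatim, used as the canonical curation walk-through input.
METHYL_ACETATE_BOILING_STRINGS: tuple[str, ...] = (
    "134.4 °F at 760 mmHg (NTP, 1992)",
    "56.7 °C",
    "535.70 °C @ 760.00 mmHg (est)",
    "57 °C",
    "135 °F",
)

#: The nine solubility strings listed by PubChem for ethanol, verbatim;
#: four contain numeric tokens, five are qualitative and are discarded.
ETHANOL_SOLUBILITY_STRINGS: tuple[str, ...] = (
    "Greater than or equal to 100 mg/mL at 73 °F (NTP, 1992)",
    "1,000,000 mg/L (at 25 °C)",
    "In water, miscible/1 × 10 + 6 mg/L/at 25 °C",
    "Miscible with ethyl ether, acetone, and chloroform; soluble in benzene",
    "Miscible with many organic solvents",
    "1000.0 mg/mL",
    "Solubility in water: miscible",
    "Soluble in water",
    "Miscible",
)


def catholyte_observed_peaks() -> list[ObservedPeak]:
    """The six observed peaks of the catholyte ¹H-NMR spectrum with roles:
    2.6 ppm is the DMSO reference, 4.9 ppm the water solvent."""
    return [
        ObservedPeak(8.35, "singlet", "analyte"),
        ObservedPeak(4.9, "singlet", "solvent"),
        ObservedPeak(3.51, "quartet", "analyte"),
        ObservedPeak(2.6, "singlet", "reference"),
        ObservedPeak(1.83, "singlet", "analyte"),
        ObservedPeak(1.04, "triplet", "analyte"),
    ]


def mixture_demo_library() -> dict[str, list[Peak]]:
    """A planted peak library for the catholyte spectrum.

    Formic acid, acetic acid, ethanol and ethoxyethane carry peaks inside the
    ±0.2 ppm windows of the observed analyte peaks with matching
    multiplicities; three decoys are rejected for different reasons (peak
    outside every window; wrong multiplicity; two peaks crowding a single
    window).  The ethanol entry also carries a minor peak (intensity below
    20% of its strongest) that the pruning step must discard — if kept, it
    would fall outside every analyte window and wrongly reject ethanol.
    """
    return {
        "formic acid": [Peak(8.30, 100.0, "singlet")],
        "acetic acid": [Peak(1.90, 100.0, "singlet")],
        "ethanol": [
            Peak(3.55, 80.0, "quartet"),
            Peak(1.10, 100.0, "triplet"),
            Peak(5.30, 10.0, "singlet"),  # minor; pruned at the 20% threshold
        ],
        "ethoxyethane": [
            Peak(3.40, 90.0, "quartet"),
            Peak(1.15, 100.0, "triplet"),
        ],
        "decoy far": [Peak(6.00, 100.0, "singlet")],
        "decoy multiplicity": [Peak(8.30, 100.0, "doublet")],
        "decoy crowded": [Peak(1.70, 100.0, "singlet"), Peak(1.95, 90.0, "singlet")],
    }


#: Synthetic classification tree in the neutral provider schema
#: (identifier -> {label, parents}).
SYNTHETIC_CLASS_TREE: dict[str, dict] = {
    "cls:root": {"label": "chemical entity", "parents": []},
    "cls:hydrocarbon": {"label": "hydrocarbon", "parents": ["cls:root"]},
    "cls:alkane": {"label": "alkane", "parents": ["cls:hydrocarbon"]},
    "cls:alkene": {"label": "alkene", "parents": ["cls:hydrocarbon"]},
    "cls:oxy": {"label": "organic oxygen compound", "parents": ["cls:root"]},
    "cls:alcohol": {"label": "alcohol", "parents": ["cls:oxy"]},
    "cls:alkanol": {"label": "alkanol", "parents": ["cls:alcohol"]},
}

#: Boiling-point trend coefficients (a, b) of T_b = a·n^(1/3) + b per class,
#: kelvin; magnitudes chosen to resemble light-hydrocarbon series.
TREND_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "alkane": (170.0, -60.0),
    "alkene": (172.0, -58.0),
    "alkanol": (175.0, 45.0),
}

_GHS_POOL: tuple[tuple[str, str], ...] = (
    ("H225", "Highly flammable liquid and vapour"),
    ("H302", "Harmful if swallowed"),
    ("H319", "Causes serious eye irritation"),
    ("H350", "May cause cancer"),
    ("H360", "May damage fertility or the unborn child"),
)

_USE_POOL: tuple[str, ...] = ("solvent", "fuel", "chemical intermediate", "reagent")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic fixture parameters; the seed fully determines output."""

    seed: int
    n_species: int = 30
    property_dialect_mix: Mapping[str, float] = field(
        default_factory=lambda: {"K": 1.0, "C": 1.0, "F_cond": 1.0, "C_cond": 1.0}
    )
    outlier_rate: float = 0.1
    noise_sd_K: float = 2.0
    nmr_rate: float = 0.75
    untagged_rate: float = 0.2
    tree_depth: int = 3
    branching: int = 2
    planted_mixture: tuple[str, ...] = ()
    jitter_ppm: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.outlier_rate, self.nmr_rate, self.untagged_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, purpose: str) -> np.random.Generator:
        """One pseudo-random stream per artifact, keyed by (seed, purpose)."""
        return np.random.default_rng([self.seed, zlib.crc32(purpose.encode())])


@dataclass(frozen=True)
class GeneratedPropertyString:
    text: str
    rendered_value: float  # value the string encodes, in the dialect's unit
    is_outlier: bool


def _render_temperature(dialect: str, kelvin: float) -> tuple[str, float]:
    if dialect == "K":
        v = round(kelvin, 2)
        return f"{v} K", v
    if dialect == "C":
        v = round(kelvin - 273.15, 1)
        return f"{v} °C", v
    if dialect == "C_cond":
        v = round(kelvin - 273.15, 2)
        return f"{v} °C @ 760.00 mmHg", v
    if dialect == "F_cond":
        v = round((kelvin - 273.15) * 9.0 / 5.0 + 32.0, 1)
        return f"{v} °F at 760 mmHg (NTP, 1992)", v
    raise ValueError(f"unknown temperature dialect {dialect!r}")


def _render_concentration(dialect: str, kg_m3: float) -> tuple[str, float]:
    if dialect == "mgL_cond":
        v = round(kg_m3 * 1000.0, 1)
        return f"{v:,.1f} mg/L (at 25 °C)", v
    if dialect == "sci":
        v = round(kg_m3 * 1000.0, 1)
        exponent = max(int(np.floor(np.log10(max(v, 1e-12)))), 0)
        mantissa = round(v / 10**exponent, 3)
        return f"{mantissa} × 10 + {exponent} mg/L", mantissa * 10**exponent
    if dialect == "mgmL":
        v = round(kg_m3, 2)
        return f"{v} mg/mL", v
    raise ValueError(f"unknown concentration dialect {dialect!r}")


def gen_property_strings(
    true_value: float,
    kind: str,
    n: int,
    spec: FixtureSpec,
    *,
    purpose: str = "property-strings",
) -> list[GeneratedPropertyString]:
    """Render ``true_value`` as ``n`` heterogeneous source strings.

    Values are expressed in mixed unit dialects (rounding keeps each within
    0.5% of the truth); with probability ``spec.outlier_rate`` a string
    renders a far-off value (×2–×3), recorded in the ground truth.
    """
    if n < 1:
        raise ValueError("need n >= 1 strings")
    rng = spec.rng(f"{purpose}:{kind}:{true_value}")
    if kind in ("BoilingPoint", "MeltingPoint", "FlashPoint"):
        dialects = [d for d in spec.property_dialect_mix if d in ("K", "C", "C_cond", "F_cond")]
        render = _render_temperature
    elif kind == "Solubility":
        dialects = ["mgL_cond", "sci", "mgmL"]
        render = _render_concentration
    else:
        raise ValueError(f"no string dialects defined for kind {kind!r}")
    weights = np.asarray(
        [spec.property_dialect_mix.get(d, 1.0) for d in dialects], dtype=float
    )
    weights /= weights.sum()
    out = []
    for _ in range(n):
        dialect = dialects[int(rng.choice(len(dialects), p=weights))]
        is_outlier = bool(rng.random() < spec.outlier_rate)
        value = true_value * float(rng.uniform(2.0, 3.0)) if is_outlier else true_value
        text, rendered = render(dialect, value)
        out.append(GeneratedPropertyString(text, rendered, is_outlier))
    return out


def _chain_atoms_bonds(cls: str, n_c: int, rng: np.random.Generator):
    """Heavy-atom skeleton: a carbon chain, one double bond for alkenes,
    a terminal oxygen for alkanols.  Hydrogens stay implicit."""
    from .model import Atom, AtomicBond

    atoms = [Atom(index=i + 1, element="C") for i in range(n_c)]
    bonds = []
    double_at = int(rng.integers(1, n_c)) if (cls == "alkene" and n_c > 1) else None
    for i in range(1, n_c):
        order = 2 if double_at == i else 1
        bonds.append(AtomicBond(atom_a=i, atom_b=i + 1, order=order))
    if cls == "alkene" and n_c == 1:  # degenerate; not generated in practice
        pass
    if cls == "alkanol":
        atoms.append(Atom(index=n_c + 1, element="O"))
        bonds.append(AtomicBond(atom_a=n_c, atom_b=n_c + 1, order=1))
    return atoms, bonds


def _formula_for(cls: str, n_c: int) -> EmpiricalFormula:
    if cls == "alkane":
        return EmpiricalFormula({"C": n_c, "H": 2 * n_c + 2})
    if cls == "alkene":
        return EmpiricalFormula({"C": n_c, "H": 2 * n_c})
    if cls == "alkanol":
        return EmpiricalFormula({"C": n_c, "H": 2 * n_c + 2, "O": 1})
    raise ValueError(cls)


def _molecular_weight(formula: EmpiricalFormula) -> float:
    return round(sum(ATOMIC_MASS[e] * n for e, n in formula.counts.items()), 3)


@dataclass
class SyntheticLibrary:
    """Generated provider payloads plus the ground truth that made them."""

    spec: FixtureSpec
    provider: InMemoryProvider
    keys: list[str]
    ground_truth: pd.DataFrame

    def populate(self, store: SpeciesStore) -> list[str]:
        """Ingest every generated species into a store; returns their IRIs."""
        rng = self.spec.rng("uuids")
        clock = lambda: datetime(2023, 4, 1, tzinfo=timezone.utc)  # noqa: E731
        from .model import new_uuid

        return [
            ingest_species(
                key,
                self.provider,
                store,
                uuid_factory=lambda: new_uuid(rng),
                clock=clock,
            )
            for key in self.keys
        ]

    def peak_library(self) -> dict[str, list[Peak]]:
        """Species label -> first-spectrum peaks, for species carrying NMR."""
        out: dict[str, list[Peak]] = {}
        for key, row in zip(self.keys, self.ground_truth.itertuples()):
            doc = self.provider.annotation_docs[key]
            nmr = [s for s in doc.get("spectra", []) if s["kind"] == "NMR1D"]
            if nmr:
                out[row.label] = [
                    Peak(p["position"], p["intensity"], p.get("multiplicity"))
                    for p in nmr[0]["peaks"]
                ]
        return out


def gen_species_library(spec: FixtureSpec) -> SyntheticLibrary:
    """Generate ``spec.n_species`` species as provider payloads.

    Each species belongs to one of alkane/alkene/alkanol with 1–12 carbons
    (alkenes need ≥ 2); its boiling point follows the class's cube-root trend
    plus Gaussian noise and is rendered as 2–5 heterogeneous strings; a
    fraction of species (``untagged_rate``) is generated *without* its class
    tag, with the truth recorded, so classification audits have known
    answers.  Deterministic per seed; class assignments are always consistent
    with formulas.
    """
    rng = spec.rng("library")
    computed_docs: dict[str, dict] = {}
    annotation_docs: dict[str, dict] = {}
    rows = []
    keys = []
    for i in range(spec.n_species):
        cls = ("alkane", "alkene", "alkanol")[int(rng.integers(0, 3))]
        n_c = int(rng.integers(2 if cls == "alkene" else 1, 13))
        formula = _formula_for(cls, n_c)
        label = formula.hill()
        a, b = TREND_COEFFICIENTS[cls]
        tb_true = a * n_c ** (1.0 / 3.0) + b + float(rng.normal(0.0, spec.noise_sd_K))
        key = f"InChI=1S/{label}/synthetic-{spec.seed}-{i}"
        keys.append(key)
        atoms, bonds = _chain_atoms_bonds(cls, n_c, rng)
        computed_docs[key] = {
            "locator": f"https://fixtures.invalid/record/{spec.seed}/{i}",
            "identifiers": {
                "InChI": key,
                "InChIKey": f"SYNTH{spec.seed:04d}{i:06d}",
                "IUPACName": f"synthetic {cls} {n_c}",
                "SMILES": "C" * n_c + ("O" if cls == "alkanol" else ""),
                "MolecularFormula": label,
            },
            "properties": {
                "MolecularWeight": {"value": _molecular_weight(formula), "unit": "g/mol"},
                "Charge": {"value": 0.0, "unit": "e"},
            },
            "atoms": [{"index": at.index, "element": at.element} for at in atoms],
            "bonds": [
                {"atom_a": bd.atom_a, "atom_b": bd.atom_b, "order": bd.order}
                for bd in bonds
            ],
        }
        n_strings = int(rng.integers(2, 6))
        strings = gen_property_strings(
            tb_true, "BoilingPoint", n_strings, spec, purpose=f"strings:{i}"
        )
        untagged = bool(rng.random() < spec.untagged_rate)
        has_nmr = bool(rng.random() < spec.nmr_rate)
        spectra = []
        if has_nmr:
            n_peaks = int(rng.integers(1, 5))
            peaks = [
                {
                    "position": round(float(rng.uniform(0.5, 10.0)), 2),
                    "intensity": round(float(rng.uniform(25.0, 100.0)), 1),
                    "multiplicity": [None, "singlet", "doublet", "triplet", "quartet"][
                        int(rng.integers(0, 5))
                    ],
                }
                for _ in range(n_peaks)
            ]
            if rng.random() < 0.3:  # a minor peak the pruning step removes
                peaks.append(
                    {
                        "position": round(float(rng.uniform(0.5, 10.0)), 2),
                        "intensity": round(float(rng.uniform(1.0, 4.0)), 1),
                        "multiplicity": None,
                    }
                )
            spectra.append(
                {"kind": "NMR1D", "solvent": "DMSO-d6", "frequency": 400.0,
                 "peaks": peaks}
            )
        ghs = []
        if rng.random() < 0.25:
            code, text = _GHS_POOL[int(rng.integers(0, len(_GHS_POOL)))]
            ghs.append({"code": code, "text": text})
        annotation_docs[key] = {
            "locator": f"https://fixtures.invalid/annotation/{spec.seed}/{i}",
            "experimental_properties": [
                {
                    "kind": "BoilingPoint",
                    "string": s.text,
                    "source": {
                        "label": f"synthetic source {j}",
                        "locator": f"https://fixtures.invalid/src/{i}/{j}",
                    },
                }
                for j, s in enumerate(strings)
            ],
            "classes": [] if untagged else [f"cls:{cls}"],
            "synonyms": [f"synthetic-{cls}-{n_c}"],
            "uses": [_USE_POOL[int(rng.integers(0, len(_USE_POOL)))]],
            "ghs": ghs,
            "spectra": spectra,
        }
        rows.append(
            {
                "label": label,
                "key": key,
                "cls": cls,
                "tagged": not untagged,
                "n_carbon": n_c,
                "tb_true_K": tb_true,
                "n_strings": n_strings,
                "outlier_strings": tuple(s.text for s in strings if s.is_outlier),
                "has_nmr": has_nmr,
                "ghs_codes": tuple(g["code"] for g in ghs),
            }
        )
    provider = InMemoryProvider(
        computed_docs=computed_docs,
        annotation_docs=annotation_docs,
        classes=dict(SYNTHETIC_CLASS_TREE),
        label="synthetic fixture provider",
    )
    return SyntheticLibrary(
        spec=spec, provider=provider, keys=keys, ground_truth=pd.DataFrame(rows)
    )


def gen_mixture_spectrum(
    library: Mapping[str, Sequence[Peak]],
    planted: Sequence[str],
    spec: FixtureSpec,
    *,
    prune_threshold: float = 0.20,
) -> list[ObservedPeak]:
    """Observed peak list for a mixture of ``planted`` library species.

    The union of the planted species' retained (major) peaks, jittered
    uniformly within ±``spec.jitter_ppm`` (default 0.1 ppm, half the matching
    window), plus a reference peak at 2.6 ppm and a solvent peak at 4.9 ppm
    with their roles set.  Planted species must exist in the library and have
    peaks.
    """
    from .analysis import prune_minor_peaks

    rng = spec.rng("mixture")
    observed = [
        ObservedPeak(2.6, "singlet", "reference"),
        ObservedPeak(4.9, "singlet", "solvent"),
    ]
    for name in planted:
        if name not in library or not library[name]:
            raise ValueError(f"planted species {name!r} has no recorded spectrum")
        for peak in prune_minor_peaks(library[name], prune_threshold):
            jitter = float(rng.uniform(-spec.jitter_ppm, spec.jitter_ppm))
            observed.append(
                ObservedPeak(peak.position + jitter, peak.multiplicity, "analyte")
            )
    return observed


def gen_random_species(rng: np.random.Generator) -> "Species":
    """A randomized species exercising every optional field of the model.

    Used by round-trip and shape-validation property tests: atoms with and
    without coordinates, multi-order bonds, several identifier kinds,
    properties with original strings / acquisition dates / reference states,
    recommended records, classes with parents, GHS codes, uses, and NMR and
    MS spectra.
    """
    from .model import (
        Atom,
        AtomicBond,
        GHSStatement,
        IdentifierRecord,
        PropertyRecord,
        Provenance,
        ReferenceState,
        Species,
        SpectrumRecord,
        new_uuid,
        RECOMMENDED_PROVENANCE_LABEL,
    )

    n_c = int(rng.integers(1, 9))
    has_o = bool(rng.random() < 0.5)
    formula = EmpiricalFormula(
        {"C": n_c, "H": 2 * n_c + 2, **({"O": 1} if has_o else {})}
    )
    uuid = new_uuid(rng)
    prov = Provenance(label="random source", locator=f"https://fixtures.invalid/{uuid}")
    atoms = [
        Atom(
            index=i + 1,
            element="C",
            x=round(float(rng.normal()), 4) if rng.random() < 0.5 else None,
        )
        for i in range(n_c)
    ]
    bonds = [
        AtomicBond(i, i + 1, order=int(rng.integers(1, 3)))
        for i in range(1, n_c)
    ]
    identifiers = [
        IdentifierRecord("InChI", f"InChI=1S/{formula.hill()}/rand-{uuid}", prov),
        IdentifierRecord("SMILES", "C" * n_c, prov),
    ]
    properties = []
    for kind, unit, scale in (
        ("BoilingPoint", "K", 400.0),
        ("Solubility", "kg/m³", 50.0),
    ):
        n_rec = int(rng.integers(1, 4))
        for idx in range(1, n_rec + 1):
            ref = None
            if kind == "BoilingPoint" and rng.random() < 0.5:
                ref = ReferenceState("pressure", 101.325, "kPa")
            properties.append(
                PropertyRecord(
                    kind=kind,
                    index=idx,
                    value=round(float(rng.uniform(0.5, 1.5)) * scale, 3),
                    unit=unit,
                    provenance=prov,
                    original_string=f"raw {idx}" if rng.random() < 0.5 else None,
                    date_acquired=datetime(2023, 4, int(rng.integers(1, 28)),
                                           tzinfo=timezone.utc),
                    reference_state=ref,
                )
            )
        if rng.random() < 0.5:
            properties.append(
                PropertyRecord(
                    kind=kind,
                    index=n_rec + 1,
                    value=properties[-1].value,
                    unit=unit,
                    provenance=Provenance(label=RECOMMENDED_PROVENANCE_LABEL),
                    is_recommended=True,
                )
            )
    from .model import ChemicalClass

    classes = []
    if rng.random() < 0.7:
        classes.append(
            ChemicalClass(
                iri="http://www.theworldavatar.com/kg/ontospecies/ChemicalClass_rt",
                label="chemical entity",
            )
        )
        k = int(rng.integers(0, 5))
        classes.append(
            ChemicalClass(
                iri=f"http://www.theworldavatar.com/kg/ontospecies/ChemicalClass_c{k}",
                label=f"class {k}",
                parents=frozenset({classes[0].iri}),
                source_id=f"cls:rand{k}",
            )
        )
    ghs = (
        [GHSStatement(code="H225", text="Highly flammable liquid and vapour")]
        if rng.random() < 0.5
        else []
    )
    spectra = []
    if rng.random() < 0.8:
        spectra.append(
            SpectrumRecord(
                kind="NMR1D",
                peaks=tuple(
                    Peak(
                        position=round(float(rng.uniform(0.5, 10.0)), 2),
                        intensity=round(float(rng.uniform(1.0, 100.0)), 1),
                        multiplicity=[None, "singlet", "triplet"][int(rng.integers(0, 3))],
                    )
                    for _ in range(int(rng.integers(1, 4)))
                ),
                solvent="DMSO-d6",
                frequency=400.0,
            )
        )
    if rng.random() < 0.3:
        spectra.append(
            SpectrumRecord(
                kind="MS",
                peaks=(Peak(position=round(float(rng.uniform(10, 200)), 1),
                            intensity=100.0),),
                ionization_mode="EI",
            )
        )
    return Species(
        uuid=uuid,
        formula=formula,
        alt_labels=frozenset({f"synonym-{uuid[:8]}"} if rng.random() < 0.6 else set()),
        atoms=atoms,
        bonds=bonds,
        identifiers=identifiers,
        properties=properties,
        classes=classes,
        ghs_statements=ghs,
        uses=("solvent",) if rng.random() < 0.5 else (),
        spectra=spectra,
    )


def gen_class_dag(spec: FixtureSpec) -> dict[str, dict]:
    """Random classification DAG in the provider schema.

    Nodes are layered ``tree_depth`` deep with ``branching`` nodes per layer;
    each node draws 1–2 parents from strictly higher layers, so the result is
    acyclic by construction.
    """
    rng = spec.rng("class-dag")
    nodes: dict[str, dict] = {"n0": {"label": "root", "parents": []}}
    layers = [["n0"]]
    counter = 1
    for depth in range(1, spec.tree_depth + 1):
        layer = []
        above = [n for lay in layers for n in lay]
        for _ in range(spec.branching):
            name = f"n{counter}"
            counter += 1
            k = int(rng.integers(1, min(2, len(above)) + 1))
            parents = sorted(
                {above[int(j)] for j in rng.choice(len(above), size=k, replace=False)}
            )
            nodes[name] = {"label": f"class {name}", "parents": parents}
            layer.append(name)
        layers.append(layer)
    return nodes
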