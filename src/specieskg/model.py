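"""Typed domain model for chemical species.

A :class:`Species` aggregates everything the knowledge graph records about one
chemical entity: its empirical formula (used as the canonical label, rendered
in Hill notation), atoms and bonds, textual identifiers (InChI, SMILES, CAS
number, ...), provenance-tracked property values, classification-hierarchy
memberships, GHS hazard statements, uses and spectra.  Every value-bearing
record carries a :class:`Provenance` so that numbers in the graph can always
be traced back to their source.
"""

from __future__ import annotations

import re
import uuid as _uuid
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

from .elements import ELEMENT_SYMBOLS
from .units import CANONICAL_UNIT_FOR_DIMENSION, PROPERTY_DIMENSIONS

__all__ = [
    "FormulaError",
    "EmpiricalFormula",
    "parse_formula",
    "formula_matches",
    "count_double_bonds",
    "Atom",
    "AtomicBond",
    "Provenance",
    "IdentifierRecord",
    "ReferenceState",
    "PropertyRecord",
    "ChemicalClass",
    "GHSStatement",
    "Peak",
    "SpectrumRecord",
    "Species",
    "new_uuid",
    "RECOMMENDED_PROVENANCE_LABEL",
]

#: Provenance label carried by curated (recommended) property records.
RECOMMENDED_PROVENANCE_LABEL = "PubChem agent"

MULTIPLICITIES = frozenset({"singlet", "doublet", "triplet", "quartet", "multiplet"})

SPECTRUM_KINDS = frozenset({"NMR1D", "NMR2D", "MS"})


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula text."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class EmpiricalFormula:
    """Element counts of a molecular formula, rendered in Hill notation."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        for element, n in counts.items():
            if element not in ELEMENT_SYMBOLS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {element} must be a positive integer")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmpiricalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.counts)

    def hill(self) -> str:
        """Hill-notation rendering: C first, then H, then others alphabetically.

        Carbon-free formulas are rendered fully alphabetically, per convention.
        """
        counts = dict(self.counts)
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order.extend(sorted(e for e in counts if e not in ("C", "H")))
        else:
            order.extend(sorted(counts))
        return "".join(
            f"{e}{counts[e]}" if counts[e] != 1 else e for e in order
        )

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> EmpiricalFormula:
    """Parse formula text like ``"C2H6O"`` into element counts.

    An absent count means 1; repeated element symbols are summed.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in ELEMENT_SYMBOLS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return EmpiricalFormula(counts)


#: Formula patterns used by the class-audit rules.  ``alkane``: CnH2n+2;
#: ``alkene``: CnH2n; ``alkanol``: CnH2n+2O; ``bounded_CHO``: organic C/H/O
#: formula with optional upper bounds on the carbon and oxygen counts.
FORMULA_PATTERNS = ("alkane", "alkene", "alkanol", "bounded_CHO")


def formula_matches(
    formula: EmpiricalFormula,
    pattern: str,
    *,
    x_max: Optional[int] = None,
    z_max: Optional[int] = None,
) -> bool:
    """True iff the formula satisfies the named pattern exactly.

    Patterns require the exact element set: an oxygen-containing formula never
    matches the alkene pattern, for example.  For ``bounded_CHO`` the formula
    must contain C and H, may contain O, no other elements, and respects the
    strict bounds ``C < x_max`` and ``O < z_max`` when given.
    """
    c, h, o = formula["C"], formula["H"], formula["O"]
    elements = formula.elements
    if pattern == "alkane":
        return elements == {"C", "H"} and c >= 1 and h == 2 * c + 2
    if pattern == "alkene":
        return elements == {"C", "H"} and c >= 1 and h == 2 * c
    if pattern == "alkanol":
        return elements == {"C", "H", "O"} and c >= 1 and h == 2 * c + 2 and o == 1
    if pattern == "bounded_CHO":
        if not elements <= {"C", "H", "O"} or c < 1 or h < 1:
            return False
        if x_max is not None and c >= x_max:
            return False
        if z_max is not None and o >= z_max:
            return False
        return True
    raise ValueError(f"unknown formula pattern {pattern!r}")


@dataclass(frozen=True)
class Atom:
    """One atom of a species; coordinates (Å) are optional."""

    index: int
    element: str
    x: Optional[float] = None
    y: Optional[float] = None
    z: Optional[float] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("atom index is 1-based")
        if self.element not in ELEMENT_SYMBOLS:
            raise ValueError(f"unknown element symbol {self.element!r}")


@dataclass(frozen=True)
class AtomicBond:
    """Unordered bond between two atom indices with integer bond order."""

    atom_a: int
    atom_b: int
    order: int = 1

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError("a bond must join two distinct atoms")
        if self.order < 1:
            raise ValueError("bond order must be a positive integer")
        if self.atom_a > self.atom_b:  # canonicalize the unordered pair
            a, b = self.atom_b, self.atom_a
            object.__setattr__(self, "atom_a", a)
            object.__setattr__(self, "atom_b", b)


def count_double_bonds(bonds: Iterable[AtomicBond]) -> int:
    """Number of bonds with order exactly 2."""
    return sum(1 for b in bonds if b.order == 2)


@dataclass(frozen=True)
class Provenance:
    """Source attribution: a label and/or a locator (URL or DOI)."""

    label: str = ""
    locator: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.label and not self.locator:
            raise ValueError("provenance needs a label or a locator")


IDENTIFIER_KINDS = frozenset(
    {"InChI", "InChIKey", "IUPACName", "SMILES", "CAS", "MolecularFormulaText"}
)

_IDENTIFIER_KIND_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*")


@dataclass(frozen=True)
class IdentifierRecord:
    kind: str
    value: str
    provenance: Provenance

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("identifier value must be non-empty")
        if not _IDENTIFIER_KIND_RE.fullmatch(self.kind):
            raise ValueError(f"identifier kind {self.kind!r} must be alphanumeric")


@dataclass(frozen=True)
class ReferenceState:
    """Temperature (K) or pressure (kPa) at which a value was measured."""

    quantity_kind: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.quantity_kind not in ("temperature", "pressure"):
            raise ValueError("reference state is a temperature or a pressure")
        expected = "K" if self.quantity_kind == "temperature" else "kPa"
        if self.unit != expected:
            raise ValueError(f"{self.quantity_kind} reference state must be in {expected}")
        if self.value <= 0:
            raise ValueError("reference-state value must be positive")


@dataclass(frozen=True)
class PropertyRecord:
    """One value of one property kind, in its canonical unit, with provenance."""

    kind: str
    index: int
    value: float
    unit: str
    provenance: Provenance
    original_string: Optional[str] = None
    date_acquired: Optional[datetime] = None
    reference_state: Optional[ReferenceState] = None
    is_recommended: bool = False

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("property index is 1-based")
        dim = PROPERTY_DIMENSIONS.get(self.kind)
        if dim is not None and self.unit != CANONICAL_UNIT_FOR_DIMENSION[dim]:
            raise ValueError(
                f"{self.kind} records are stored in "
                f"{CANONICAL_UNIT_FOR_DIMENSION[dim]!r}, got {self.unit!r}"
            )
        if self.is_recommended and self.provenance.label != RECOMMENDED_PROVENANCE_LABEL:
            raise ValueError(
                f"recommended records carry provenance label "
                f"{RECOMMENDED_PROVENANCE_LABEL!r}"
            )


@dataclass(frozen=True)
class ChemicalClass:
    """Node in a parent-linked classification hierarchy (DAG)."""

    iri: str
    label: str
    parents: frozenset[str] = frozenset()
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", frozenset(self.parents))
        if self.iri in self.parents:
            raise ValueError(f"class {self.iri} cannot be its own parent")


_GHS_CODE_RE = re.compile(r"[A-Za-z]+\d+")


@dataclass(frozen=True)
class GHSStatement:
    code: str
    text: str = ""

    def __post_init__(self) -> None:
        if not _GHS_CODE_RE.fullmatch(self.code):
            raise ValueError(f"GHS code {self.code!r} must be letters followed by digits")


@dataclass(frozen=True)
class Peak:
    """A spectral peak: position in ppm (NMR) or m/z (MS)."""

    position: float
    intensity: float = 1.0
    multiplicity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")
        if self.multiplicity is not None and self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")


@dataclass(frozen=True)
class SpectrumRecord:
    kind: str
    peaks: tuple[Peak, ...]
    sequence_number: int = 1
    solvent: Optional[str] = None
    frequency: Optional[float] = None
    ionization_mode: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.sequence_number < 1:
            raise ValueError("sequence_number is 1-based")
        if self.kind.startswith("NMR") and self.ionization_mode is not None:
            raise ValueError("NMR spectra carry no ionization mode")
        if self.kind == "MS" and (self.solvent is not None or self.frequency is not None):
            raise ValueError("mass spectra carry no solvent or frequency")


def new_uuid(rng=None) -> str:
    """A fresh random 128-bit identifier in canonical UUID text form.

    Accepts a :class:`numpy.random.Generator` (or anything with ``bytes``-like
    ``integers``) so fixture generation is reproducible; without one, uses the
    standard library's UUID4.
    """
    if rng is None:
        return str(_uuid.uuid4())
    raw = bytes(int(x) for x in rng.integers(0, 256, size=16))
    return str(_uuid.UUID(bytes=raw, version=4))


@dataclass
class Species:
    """Aggregate record for one chemical species.

    Collections are normalized to deterministically sorted tuples at
    construction so that two species with the same content compare equal
    regardless of input order (peak order within a spectrum is meaningful and
    is preserved).
    """

    uuid: str
    formula: EmpiricalFormula
    alt_labels: frozenset[str] = frozenset()
    atoms: Sequence[Atom] = ()
    bonds: Sequence[AtomicBond] = ()
    identifiers: Sequence[IdentifierRecord] = ()
    properties: Sequence[PropertyRecord] = ()
    classes: Sequence[ChemicalClass] = ()
    ghs_statements: Sequence[GHSStatement] = ()
    uses: Sequence[str] = ()
    spectra: Sequence[SpectrumRecord] = ()

    def __post_init__(self) -> None:
        if not self.uuid:
            raise ValueError("species uuid must be non-empty")
        self.alt_labels = frozenset(self.alt_labels)
        self.atoms = tuple(sorted(self.atoms, key=lambda a: a.index))
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("atom indices must be unique")
        self.bonds = tuple(sorted(set(self.bonds), key=lambda b: (b.atom_a, b.atom_b)))
        self.identifiers = tuple(
            sorted(self.identifiers, key=lambda i: (i.kind, i.value))
        )
        self.properties = tuple(
            sorted(self.properties, key=lambda p: (p.kind, p.index))
        )
        by_kind: dict[str, list[int]] = {}
        for p in self.properties:
            by_kind.setdefault(p.kind, []).append(p.index)
        for kind, idxs in by_kind.items():
            if idxs != list(range(1, len(idxs) + 1)):
                raise ValueError(f"{kind} indices must be consecutive from 1, got {idxs}")
        self.classes = tuple(sorted(self.classes, key=lambda c: c.iri))
        self.ghs_statements = tuple(
            sorted(self.ghs_statements, key=lambda g: (g.code, g.text))
        )
        self.uses = tuple(sorted(set(self.uses)))
        self.spectra = tuple(
            sorted(self.spectra, key=lambda s: (s.kind, s.sequence_number))
        )

    @property
    def label(self) -> str:
        """Canonical label: the Hill rendering of the molecular formula."""
        return self.formula.hill()

    def properties_of_kind(self, kind: str) -> tuple[PropertyRecord, ...]:
        return tuple(p for p in self.properties if p.kind == kind)

    def recommended(self, kind: str) -> Optional[PropertyRecord]:
        for p in self.properties_of_kind(kind):
            if p.is_recommended:
                return p
        return None
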