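"""RDF vocabulary: TBox namespace, predicates and classes used by the emitter."""

from rdflib import Namespace
from rdflib.namespace import RDF, RDFS, SKOS, XSD  # noqa: F401  (re-exported)

#: Terminology (TBox) namespace for classes and predicates.
OS = Namespace("http://www.theworldavatar.com/ontology/ontospecies/OntoSpecies.owl#")

# classes
SPECIES = OS.Species
ATOM = OS.Atom
ATOMIC_BOND = OS.AtomicBond
IDENTIFIER = OS.Identifier
PROPERTY = OS.Property
REFERENCE_STATE = OS.ReferenceState
CHEMICAL_CLASS = OS.ChemicalClass
GHS_HAZARD_STATEMENT = OS.GHSHazardStatement
USE = OS.Use
REFERENCE = OS.Reference
SPECTRAL_INFORMATION = OS.SpectralInformation
PEAK = OS.Peak

#: spectrum kind -> (ABox class-type name, TBox class)
SPECTRUM_CLASSES = {
    "NMR1D": ("1DNMRSpectra", OS["1DNMRSpectra"]),
    "NMR2D": ("2DNMRSpectra", OS["2DNMRSpectra"]),
    "MS": ("MassSpectrometry", OS.MassSpectrometry),
}

# predicates
HAS_ATOM = OS.hasAtom
HAS_ATOMIC_BOND = OS.hasAtomicBond
HAS_IDENTIFIER = OS.hasIdentifier
HAS_PROPERTY = OS.hasProperty
HAS_CHEMICAL_CLASS = OS.hasChemicalClass
HAS_PARENT_CLASS = OS.hasParentClass
HAS_GHS_STATEMENT = OS.hasGHSHazardStatement
HAS_USE = OS.hasUse
HAS_SPECTRAL_INFORMATION = OS.hasSpectralInformation
HAS_PEAK = OS.hasPeak
HAS_PROVENANCE = OS.hasProvenance
HAS_REFERENCE_STATE = OS.hasReferenceState
HAS_BOND_ORDER = OS.hasBondOrder

VALUE = OS.value
UNIT = OS.unit
ORIGINAL_DATA_STRING = OS.originalDataString
DATE_OF_ACQUISITION = OS.dateOfAcquisition
IS_RECOMMENDED = OS.isRecommended
QUANTITY_KIND = OS.quantityKind
ATOM_INDEX = OS.atomIndex
ELEMENT = OS.element
X_COORDINATE = OS.XCoordinate
Y_COORDINATE = OS.YCoordinate
Z_COORDINATE = OS.ZCoordinate
BOND_ATOM_A = OS.bondAtomA
BOND_ATOM_B = OS.bondAtomB
SOURCE_IDENTIFIER = OS.sourceIdentifier
LOCATOR = OS.locator
SEQUENCE_NUMBER = OS.sequenceNumber
SOLVENT = OS.solvent
FREQUENCY = OS.frequency
IONIZATION_MODE = OS.ionizationMode
INTENSITY = OS.intensity
MULTIPLICITY = OS.multiplicity
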