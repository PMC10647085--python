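"""IRI minting conventions for instance (ABox) nodes.

Species nodes are named ``<ns>Species_<UUID>``.  Instances attached to a
species (a boiling point, an IUPAC name, ...) combine their class-type name,
a 1-based index and the species UUID: ``<ns>BoilingPoint_1_Species_<UUID>``.
Free-standing concepts (a use, a reference) are ``<ns><ClassTypeName>_<id>``.
All minting is deterministic in its inputs.
"""

from __future__ import annotations

import hashlib
import re

__all__ = [
    "DEFAULT_NAMESPACE",
    "mint_species_iri",
    "mint_attached_iri",
    "mint_free_iri",
    "stable_id",
]

DEFAULT_NAMESPACE = "http://www.theworldavatar.com/kg/ontospecies/"

_UUID_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-]*")
_CLASS_NAME_RE = re.compile(r"[A-Za-z0-9]+")


def _check_uuid(uuid: str) -> str:
    if not isinstance(uuid, str) or not _UUID_RE.fullmatch(uuid):
        raise ValueError(f"malformed uuid {uuid!r}")
    return uuid


def _check_class_name(name: str) -> str:
    if not name or not _CLASS_NAME_RE.fullmatch(name):
        raise ValueError(f"malformed class-type name {name!r}")
    return name


def mint_species_iri(uuid: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return f"{namespace}Species_{_check_uuid(uuid)}"


def mint_attached_iri(
    class_name: str, index: int, species_uuid: str, namespace: str = DEFAULT_NAMESPACE
) -> str:
    if index < 1:
        raise ValueError("attached-instance index is 1-based")
    return (
        f"{namespace}{_check_class_name(class_name)}_{index}"
        f"_Species_{_check_uuid(species_uuid)}"
    )


def mint_free_iri(class_name: str, uuid: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return f"{namespace}{_check_class_name(class_name)}_{_check_uuid(uuid)}"


def stable_id(*parts: str) -> str:
    """Short deterministic identifier for shared nodes (provenances, uses)."""
    digest = hashlib.sha1("\x1f".join(parts).encode("utf-8")).hexdigest()
    return digest[:12]
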