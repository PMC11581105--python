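"""Versioned annotation schema for nanoscale connectomics metadata.

A :class:`Schema` is a set of annotation classes (neuron, soma, synapse, ...)
with typed properties and extensible enumerations.  Classes carry exactly one
of eight category tags (neuron type, soma, cellular compartments/organelles,
compartment-specific properties, synapse, gap junction, organelle-specific
classes, synapse-associated organelles).  Two structural rules are enforced:

* **single-home** — a property name belongs to exactly one class, schema-wide,
  so the same entity is never duplicated across classes as an optional field;
* **synonym disjointness** — a display term ("cell body") maps to at most one
  class, so vocabulary normalization is a function.

Schemas serialize to a deterministic JSON dialect (top-level keys
``standard``, ``version``, ``classes``, ``enums``, ``extensions``) so that
serialize -> load is the identity and serialization is byte-stable.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator

STANDARD_NAME = "BENCHMARK-annotation"

_TOKEN_RE = re.compile(r"^[a-z][a-z0-9_]*$")
_SEMVER_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)$")


class SchemaError(ValueError):
    """A schema violates a structural invariant, or cannot be parsed."""


class PropertyType(str, Enum):
    """Closed set of property value types.

    ``spatial_point`` carries a :class:`BoundSpatialPoint` payload and
    ``identifier`` an opaque string/integer ID; together they cover the
    spatial-linkage and ID-valued fields the standard needs beyond the
    primitive scalar types.
    """

    INTEGER = "integer"
    FLOAT = "float"
    STRING = "string"
    ENUMERATION = "enumeration"
    BOOLEAN = "boolean"
    SPATIAL_POINT = "spatial_point"
    IDENTIFIER = "identifier"


class CategoryTag(str, Enum):
    """The eight annotation categories, one per diagram color."""

    NEURON_TYPE = "neuron_type"
    SOMA = "soma"
    CELLULAR_COMPARTMENT_ORGANELLE = "cellular_compartment_organelle"
    COMPARTMENT_SPECIFIC_PROPERTY = "compartment_specific_property"
    SYNAPSE = "synapse"
    GAP_JUNCTION = "gap_junction"
    ORGANELLE_SPECIFIC_CLASS = "organelle_specific_class"
    SYNAPSE_ASSOCIATED_ORGANELLE = "synapse_associated_organelle"


def term_key(term: str) -> str:
    """Canonical matching key for a display term or class token.

    Lowercases, trims, collapses internal whitespace and folds ``_``/``-``
    to single spaces, so "Cell Body", "cell_body" and " cell  body " all
    compare equal.
    """
    return re.sub(r"[\s_\-]+", " ", term.strip().lower())


@dataclass(frozen=True)
class EnumValue:
    name: str
    code: int

    def to_json(self) -> dict[str, Any]:
        return {"name": self.name, "code": self.code}


@dataclass(frozen=True)
class EnumSpec:
    """A named enumeration with stable (name, code) pairs.

    Codes are assigned in declaration order starting at 0 and are frozen
    across schema versions (new values append).  When ``extensible``,
    documents may carry user values namespaced with an ``x-`` prefix;
    bare values must be members.
    """

    name: str
    values: tuple[EnumValue, ...]
    extensible: bool = True

    def __post_init__(self) -> None:
        if not self.values:
            raise SchemaError(f"enum {self.name!r} must declare at least one value")
        names = [v.name.lower() for v in self.values]
        if len(set(names)) != len(names):
            raise SchemaError(f"enum {self.name!r} has case-colliding value names")
        codes = [v.code for v in self.values]
        if len(set(codes)) != len(codes) or any(c < 0 for c in codes):
            raise SchemaError(f"enum {self.name!r} has duplicate or negative codes")

    def value_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.values)

    def is_member(self, raw: Any) -> bool:
        """True if *raw* is a member name, a member code, or an ``x-`` extension."""
        if isinstance(raw, bool):
            return False
        if isinstance(raw, int):
            return raw in {v.code for v in self.values}
        if isinstance(raw, str):
            if self.extensible and raw.startswith("x-") and len(raw) > 2:
                return True
            return raw.lower() in {v.name.lower() for v in self.values}
        return False

    def to_json(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "values": [v.to_json() for v in self.values],
            "extensible": self.extensible,
        }


def make_enum(name: str, names: list[str] | tuple[str, ...], extensible: bool = True) -> EnumSpec:
    """Build an EnumSpec assigning codes in declaration order from 0."""
    return EnumSpec(name, tuple(EnumValue(n, i) for i, n in enumerate(names)), extensible)


@dataclass(frozen=True)
class PropertySpec:
    """A typed property housed under exactly one class."""

    name: str
    ptype: PropertyType
    enum_ref: str = ""
    required: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not _TOKEN_RE.match(self.name):
            raise SchemaError(f"property name {self.name!r} is not a snake_case token")
        if (self.ptype is PropertyType.ENUMERATION) != bool(self.enum_ref):
            raise SchemaError(
                f"property {self.name!r}: enum_ref must be set iff type is enumeration"
            )

    def to_json(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "type": self.ptype.value,
            "enum_ref": self.enum_ref,
            "required": self.required,
            "description": self.description,
        }


@dataclass(frozen=True)
class SchemaClass:
    """A broad annotation class with typed properties and display synonyms."""

    name: str
    category: CategoryTag
    properties: tuple[PropertySpec, ...] = ()
    synonyms: tuple[str, ...] = ()
    parent: str = ""

    def __post_init__(self) -> None:
        if not _TOKEN_RE.match(self.name):
            raise SchemaError(f"class name {self.name!r} is not a snake_case token")
        pnames = [p.name for p in self.properties]
        if len(set(pnames)) != len(pnames):
            raise SchemaError(f"class {self.name!r} declares a duplicate property name")

    def to_json(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "category": self.category.value,
            "properties": [p.to_json() for p in self.properties],
            "synonyms": list(self.synonyms),
            "parent": self.parent,
        }


@dataclass(frozen=True)
class BoundSpatialPoint:
    """A voxel coordinate bound to a segmentation segment.

    Positions are 0-based voxel indices in (x, y, z) order.  ``segment_id``
    0 is reserved for "unbound/background"; ``resolution_level`` selects the
    downsampling level of the coordinate frame.
    """

    position: tuple[float, float, float]
    segment_id: int = 0
    resolution_level: int = 0

    def __post_init__(self) -> None:
        if len(self.position) != 3 or not all(
            isinstance(c, (int, float)) and not isinstance(c, bool) and math.isfinite(c)
            for c in self.position
        ):
            raise SchemaError("position must have exactly three finite components")
        if not isinstance(self.segment_id, int) or isinstance(self.segment_id, bool) or self.segment_id < 0:
            raise SchemaError("segment_id must be a non-negative integer")
        if not isinstance(self.resolution_level, int) or self.resolution_level < 0:
            raise SchemaError("resolution_level must be a non-negative integer")

    @property
    def bound(self) -> bool:
        return self.segment_id != 0

    def to_json(self) -> dict[str, Any]:
        return {
            "position": list(self.position),
            "segment_id": self.segment_id,
            "resolution_level": self.resolution_level,
        }

    @classmethod
    def from_json(cls, obj: Any) -> "BoundSpatialPoint":
        if not isinstance(obj, dict) or "position" not in obj:
            raise SchemaError("spatial point must be an object with a 'position' key")
        pos = obj["position"]
        if not isinstance(pos, (list, tuple)):
            raise SchemaError("position must be a 3-element array")
        return cls(
            position=tuple(pos),  # length/finiteness checked in __post_init__
            segment_id=obj.get("segment_id", 0),
            resolution_level=obj.get("resolution_level", 0),
        )


@dataclass(frozen=True)
class Schema:
    """A versioned set of annotation classes and enumerations."""

    version: str
    classes: tuple[SchemaClass, ...]
    enums: tuple[EnumSpec, ...] = ()
    extensions: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        issues = validate_schema(self)
        if issues:
            raise SchemaError("; ".join(issues))

    # -- lookups ---------------------------------------------------------

    def class_by_name(self, name: str) -> SchemaClass | None:
        for c in self.classes:
            if c.name == name:
                return c
        return None

    def enum_by_name(self, name: str) -> EnumSpec | None:
        for e in self.enums:
            if e.name == name:
                return e
        return None

    def resolve_class_term(self, term: str) -> tuple[str, str]:
        """Resolve a display term to (class name, how) with how in
        {"exact", "synonym", ""}.  Case-insensitive; folds separators and a
        trailing plural "s"."""
        key = term_key(term)
        keys = [key]
        if key.endswith("s") and len(key) > 1:
            keys.append(key[:-1])
        for k in keys:
            for c in self.classes:
                if term_key(c.name) == k:
                    return c.name, "exact"
        for k in keys:
            for c in self.classes:
                if any(term_key(s) == k for s in c.synonyms):
                    return c.name, "synonym"
        return "", ""

    def iter_properties(self) -> Iterator[tuple[SchemaClass, PropertySpec]]:
        for c in self.classes:
            for p in c.properties:
                yield c, p

    def property_home(self, property_name: str) -> str | None:
        for c, p in self.iter_properties():
            if p.name == property_name:
                return c.name
        return None

    def property_spec(self, property_name: str) -> PropertySpec | None:
        for _, p in self.iter_properties():
            if p.name == property_name:
                return p
        return None


def validate_schema(s: Schema) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    issues: list[str] = []
    if not _SEMVER_RE.match(s.version):
        issues.append(f"version {s.version!r} is not MAJOR.MINOR.PATCH semver")

    names = [c.name for c in s.classes]
    for n in sorted({n for n in names if names.count(n) > 1}):
        issues.append(f"duplicate class name {n!r}")

    # single-home: property names globally unique across classes
    homes: dict[str, list[str]] = {}
    for c in s.classes:
        for p in c.properties:
            homes.setdefault(p.name, []).append(c.name)
    for pname, cs in sorted(homes.items()):
        if len(cs) > 1:
            issues.append(
                f"single-home violation: property {pname!r} declared under classes "
                + ", ".join(repr(c) for c in cs)
            )

    # enum refs resolve
    enum_names = {e.name for e in s.enums}
    for c in s.classes:
        for p in c.properties:
            if p.enum_ref and p.enum_ref not in enum_names:
                issues.append(f"{c.name}.{p.name}: enum_ref {p.enum_ref!r} does not resolve")

    # synonyms case-insensitively disjoint across classes (and from class names)
    seen: dict[str, str] = {term_key(c.name): c.name for c in s.classes}
    for c in s.classes:
        for syn in c.synonyms:
            k = term_key(syn)
            if k in seen and seen[k] != c.name:
                issues.append(f"synonym {syn!r} of class {c.name!r} collides with {seen[k]!r}")
            seen.setdefault(k, c.name)

    # parent links: exist, no cycles
    byname = {c.name: c for c in s.classes}
    for c in s.classes:
        if c.parent and c.parent not in byname:
            issues.append(f"class {c.name!r}: parent {c.parent!r} does not exist")
    for c in s.classes:
        slow, hops = c, 0
        while slow.parent and slow.parent in byname:
            slow = byname[slow.parent]
            hops += 1
            if hops > len(s.classes):
                issues.append(f"parent cycle involving class {c.name!r}")
                break
    return issues


# ---------------------------------------------------------------------------
# built-in v1.1 schema
# ---------------------------------------------------------------------------

def builtin_schema_v1_1() -> Schema:
    """The canonical built-in v1.1 annotation schema.

    Class names are snake_case tokens; "soma" is canonical for the cell body
    (the diagram names the category "soma") with "cell body" as a synonym.
    Spine-associated identifiers live on ``synapse`` (single-home rule), and
    ``neuron`` separates the ``interneurons`` enumeration from the free-text
    ``interneuron_type`` so counts and type labels are never conflated.
    Properties beyond those mandated by the standard's examples are marked
    implementation-extension in their descriptions.
    """
    enums = (
        make_enum(
            "interneuron_status",
            ["unknown", "not_interneuron", "putative_interneuron", "interneuron"],
        ),
        make_enum("confidence_level", ["low", "medium", "high"]),
    )
    ext = "implementation-extension: "
    classes = (
        SchemaClass(
            "neuron",
            CategoryTag.NEURON_TYPE,
            properties=(
                PropertySpec("cell_id", PropertyType.IDENTIFIER, required=True,
                             description="stable cell identifier within the dataset"),
                PropertySpec("interneurons", PropertyType.ENUMERATION,
                             enum_ref="interneuron_status",
                             description="interneuron designation as a coded enumeration"),
                PropertySpec("interneuron_type", PropertyType.STRING,
                             description="free-text interneuron type label"),
            ),
        ),
        SchemaClass(
            "interneuron",
            CategoryTag.NEURON_TYPE,
            properties=(
                PropertySpec("molecular_layer", PropertyType.BOOLEAN,
                             description=ext + "molecular-layer interneuron flag"),
            ),
            parent="neuron",
        ),
        SchemaClass(
            "soma",
            CategoryTag.SOMA,
            properties=(
                PropertySpec("centroid", PropertyType.SPATIAL_POINT,
                             description=ext + "soma centroid bound to its segment"),
                PropertySpec("soma_volume_um3", PropertyType.FLOAT,
                             description=ext + "soma volume in cubic micrometers"),
            ),
            synonyms=("cell body",),
        ),
        SchemaClass(
            "axon",
            CategoryTag.CELLULAR_COMPARTMENT_ORGANELLE,
            properties=(
                PropertySpec("myelinated", PropertyType.BOOLEAN,
                             description=ext + "axon myelination flag"),
            ),
        ),
        SchemaClass(
            "dendrite",
            CategoryTag.CELLULAR_COMPARTMENT_ORGANELLE,
            properties=(
                PropertySpec("apical", PropertyType.BOOLEAN,
                             description=ext + "apical (vs basal) dendrite flag"),
            ),
        ),
        SchemaClass(
            "spine",
            CategoryTag.COMPARTMENT_SPECIFIC_PROPERTY,
            properties=(
                PropertySpec("neck_length_nm", PropertyType.FLOAT,
                             description=ext + "spine neck length in nanometers"),
            ),
        ),
        SchemaClass(
            "bouton",
            CategoryTag.COMPARTMENT_SPECIFIC_PROPERTY,
            properties=(
                PropertySpec("en_passant", PropertyType.BOOLEAN,
                             description=ext + "en-passant (passant bouton) flag"),
            ),
        ),
        SchemaClass(
            "synapse",
            CategoryTag.SYNAPSE,
            properties=(
                PropertySpec("spine_id", PropertyType.IDENTIFIER,
                             description="identifier of the associated dendritic spine"),
                PropertySpec("confidence", PropertyType.ENUMERATION,
                             enum_ref="confidence_level",
                             description=ext + "annotator confidence in the synapse call"),
                PropertySpec("vesicle_count", PropertyType.INTEGER,
                             description=ext + "number of presynaptic vesicles"),
            ),
        ),
        SchemaClass(
            "gap_junction",
            CategoryTag.GAP_JUNCTION,
            properties=(
                PropertySpec("junction_area_nm2", PropertyType.FLOAT,
                             description=ext + "junction contact area in square nanometers"),
            ),
        ),
        SchemaClass(
            "synaptic_cleft",
            CategoryTag.SYNAPSE_ASSOCIATED_ORGANELLE,
            properties=(
                PropertySpec("cleft_width_nm", PropertyType.FLOAT,
                             description=ext + "cleft width in nanometers"),
            ),
        ),
        SchemaClass(
            "spine_apparatus",
            CategoryTag.SYNAPSE_ASSOCIATED_ORGANELLE,
            properties=(
                PropertySpec("lamellae_count", PropertyType.INTEGER,
                             description=ext + "number of membrane lamellae"),
            ),
        ),
        SchemaClass(
            "region_of_interest",
            CategoryTag.CELLULAR_COMPARTMENT_ORGANELLE,
            properties=(
                PropertySpec("region_name", PropertyType.STRING, required=True,
                             description="name of the anatomical region or layer"),
                PropertySpec("atlas", PropertyType.STRING,
                             description=ext + "reference atlas the region name comes from"),
            ),
        ),
    )
    return Schema(version="1.1.0", classes=classes, enums=enums)


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def serialize_schema(s: Schema) -> str:
    """Serialize to the JSON schema dialect; deterministic (sorted keys within
    objects, declaration order within lists)."""
    doc = {
        "standard": STANDARD_NAME,
        "version": s.version,
        "classes": [c.to_json() for c in s.classes],
        "enums": [e.to_json() for e in s.enums],
        "extensions": dict(s.extensions),
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


_KNOWN_TOP_KEYS = {"standard", "version", "classes", "enums", "extensions"}


def load_schema(text: str) -> Schema:
    """Parse and validate a schema document.

    Unknown top-level keys are preserved in the schema's extensions area,
    never silently dropped.  Invariant violations raise :class:`SchemaError`
    with a class/property path in the message.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed schema document: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("schema document must be a JSON object")
    if doc.get("standard", STANDARD_NAME) != STANDARD_NAME:
        raise SchemaError(f"unrecognized standard {doc.get('standard')!r}")
    if "version" not in doc:
        raise SchemaError("schema document lacks a 'version' key")

    enums = []
    for i, e in enumerate(doc.get("enums", [])):
        try:
            enums.append(
                EnumSpec(
                    name=e["name"],
                    values=tuple(EnumValue(v["name"], v["code"]) for v in e["values"]),
                    extensible=bool(e.get("extensible", True)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"enums[{i}]: malformed enum entry ({exc})") from exc

    classes = []
    for i, c in enumerate(doc.get("classes", [])):
        path = f"classes[{i}]"
        try:
            cname = c["name"]
            props = tuple(
                PropertySpec(
                    name=p["name"],
                    ptype=PropertyType(p["type"]),
                    enum_ref=p.get("enum_ref", ""),
                    required=bool(p.get("required", False)),
                    description=p.get("description", ""),
                )
                for p in c.get("properties", [])
            )
            classes.append(
                SchemaClass(
                    name=cname,
                    category=CategoryTag(c["category"]),
                    properties=props,
                    synonyms=tuple(c.get("synonyms", [])),
                    parent=c.get("parent", ""),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed class entry ({exc})") from exc

    extensions = dict(doc.get("extensions", {}))
    for k in sorted(set(doc) - _KNOWN_TOP_KEYS):
        extensions[k] = doc[k]

    return Schema(
        version=doc["version"],
        classes=tuple(classes),
        enums=tuple(enums),
        extensions=tuple(sorted(extensions.items(), key=lambda kv: kv[0])),
    )


def resolve_property_home(s: Schema, property_name: str) -> str:
    """Return the unique class housing *property_name*.

    Raises :class:`KeyError` when the property is absent from the schema.
    """
    home = s.property_home(property_name)
    if home is None:
        raise KeyError(f"property {property_name!r} not found in schema {s.version}")
    return home
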