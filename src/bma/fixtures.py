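"""Seeded synthetic fixtures: clean and deliberately corrupted metadata.

Everything needed to exercise the standard offline is fabricated here: clean
annotation documents (always valid against their schema), a verbatim copy of
the published study-term crosswalk, dataset trees, and a defect injector that
emulates the error classes observed in hand-entered metadata — synonym drift,
misspellings, separator noise, properties placed outside their home class,
out-of-vocabulary enum values, version skew and dropped required fields.

All generators are pure functions of (inputs, seed); the seed is recorded in
every generated document's extensions area so fixtures are self-describing.
Each defect mode maps onto the detector that must fire on it:

==================  ==========================================================
mode                detector
==================  ==========================================================
synonym_swap        normalization change log (matched_via synonym/crosswalk)
misspell            UNKNOWN_CLASS error; true term recovered by suggest_terms
separator_noise     UNKNOWN_CLASS error; tokenize_list recovers the tokens
wrong_home          WRONG_HOME error naming the home class
bad_enum            ENUM_VIOLATION error
version_skew        VERSION_MISMATCH error
missing_required    MISSING_REQUIRED error
==================  ==========================================================
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field

from .documents import AnnotationDocument, AnnotationObject
from .hierarchy import DatasetTree, HierarchyLevel, HierarchyRecord, add_record
from .schema_core import (
    BoundSpatialPoint,
    CategoryTag,
    EnumSpec,
    EnumValue,
    PropertySpec,
    PropertyType,
    Schema,
    SchemaClass,
)

DEFECT_MODES = (
    "synonym_swap",
    "misspell",
    "separator_noise",
    "wrong_home",
    "bad_enum",
    "version_skew",
    "missing_required",
)

# expected detector per mode: (channel, code) where channel is "validator"
# or "normalizer"
DEFECT_DETECTORS = {
    "synonym_swap": ("normalizer", "change_log"),
    "misspell": ("validator", "UNKNOWN_CLASS"),
    "separator_noise": ("validator", "UNKNOWN_CLASS"),
    "wrong_home": ("validator", "WRONG_HOME"),
    "bad_enum": ("validator", "ENUM_VIOLATION"),
    "version_skew": ("validator", "VERSION_MISMATCH"),
    "missing_required": ("validator", "MISSING_REQUIRED"),
}

DEFAULT_EXTENT = (2048, 2048, 1024)


@dataclass(frozen=True)
class DefectSpec:
    mode: str
    rate: float

    def __post_init__(self) -> None:
        if self.mode not in DEFECT_MODES:
            raise ValueError(f"unknown defect mode {self.mode!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")


@dataclass(frozen=True)
class TruthLogEntry:
    object_id: str
    mode: str
    before: str
    after: str


@dataclass
class TruthLog:
    entries: list[TruthLogEntry] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clean document generation
# ---------------------------------------------------------------------------

def _random_value(rng: random.Random, spec: PropertySpec, schema: Schema):
    if spec.ptype is PropertyType.INTEGER:
        return rng.randint(0, 500)
    if spec.ptype is PropertyType.FLOAT:
        return round(rng.uniform(0.01, 1000.0), 3)
    if spec.ptype is PropertyType.BOOLEAN:
        return rng.random() < 0.5
    if spec.ptype is PropertyType.STRING:
        words = ("layer 2/3", "basket", "martinotti", "cortex", "thalamus", "vpm", "unknown")
        return rng.choice(words)
    if spec.ptype is PropertyType.IDENTIFIER:
        return f"seg-{rng.randint(1, 10**9)}"
    if spec.ptype is PropertyType.ENUMERATION:
        enum = schema.enum_by_name(spec.enum_ref)
        assert enum is not None
        return rng.choice(enum.value_names())
    if spec.ptype is PropertyType.SPATIAL_POINT:
        return _random_anchor(rng).to_json()
    raise AssertionError(spec.ptype)


def _random_anchor(rng: random.Random) -> BoundSpatialPoint:
    return BoundSpatialPoint(
        position=(
            float(rng.randrange(DEFAULT_EXTENT[0])),
            float(rng.randrange(DEFAULT_EXTENT[1])),
            float(rng.randrange(DEFAULT_EXTENT[2])),
        ),
        segment_id=rng.randint(1, 10**7),
        resolution_level=rng.choice((0, 0, 0, 1, 2)),
    )


def _random_object(rng: random.Random, schema: Schema, cls: SchemaClass, oid: str) -> AnnotationObject:
    props = {}
    for spec in cls.properties:
        if spec.required or rng.random() < 0.7:
            props[spec.name] = _random_value(rng, spec, schema)
    anchor = _random_anchor(rng) if rng.random() < 0.8 else None
    return AnnotationObject(id=oid, class_term=cls.name, properties=props, anchor=anchor)


def generate_documents(
    schema: Schema,
    n: int,
    seed: int,
    n_documents: int | None = None,
    dataset_path: str = "microns/minnie/em/segmentation",
) -> list[AnnotationDocument]:
    """Generate documents holding *n* clean annotation objects in total.

    Objects are sampled uniformly across the schema's classes (real volumes
    are synapse-dominated; uniform sampling maximizes per-class coverage for
    testing).  Identical (schema, n, seed) yields byte-identical serialized
    output.  When *n_documents* is omitted, objects pack 25 per document
    (at least one document, even for n == 0).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(seed)
    if n_documents is None:
        n_documents = max(1, -(-n // 25))
    if n_documents < 1:
        raise ValueError("n_documents must be >= 1")
    per_doc = [n // n_documents] * n_documents
    for i in range(n % n_documents):
        per_doc[i] += 1
    docs = []
    counter = 0
    for d, count in enumerate(per_doc):
        objects = []
        for _ in range(count):
            cls = schema.classes[rng.randrange(len(schema.classes))]
            counter += 1
            objects.append(_random_object(rng, schema, cls, f"obj-{counter:06d}"))
        docs.append(
            AnnotationDocument(
                schema_version=schema.version,
                dataset_path=dataset_path,
                objects=objects,
                extensions={"generator": {"seed": seed, "doc_index": d, "n_total": n}},
            )
        )
    return docs


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def _misspell(rng: random.Random, term: str) -> str:
    """Exactly one single-character edit, guaranteeing edit distance 1."""
    alphabet = string.ascii_lowercase
    while True:
        op = rng.choice(("insert", "delete", "substitute"))
        if op == "insert":
            i = rng.randrange(len(term) + 1)
            out = term[:i] + rng.choice(alphabet) + term[i:]
        elif op == "delete" and len(term) > 1:
            i = rng.randrange(len(term))
            out = term[:i] + term[i + 1 :]
        else:
            i = rng.randrange(len(term))
            c = rng.choice(alphabet)
            if c == term[i]:
                continue
            out = term[:i] + c + term[i:][1:]
        if out != term:
            return out


def _synonym_variants(schema: Schema, cls_name: str, crosswalk_terms: dict[str, list[str]]) -> list[str]:
    cls = schema.class_by_name(cls_name)
    variants: list[str] = []
    if cls is not None:
        variants.extend(s.title() for s in cls.synonyms)
    for t in crosswalk_terms.get(cls_name, []):
        if t.lower() != cls_name.lower():
            variants.append(t)
    return variants


def corrupt_documents(
    docs: list[AnnotationDocument],
    defects: list[DefectSpec],
    seed: int,
    schema: Schema,
    crosswalk=None,
) -> tuple[list[AnnotationDocument], TruthLog]:
    """Apply each defect mode at its rate over the eligible objects.

    Eligibility is per-mode (e.g. ``missing_required`` needs an object whose
    class declares a required property; ``synonym_swap`` needs a class with a
    printed synonym).  Every injected defect is recorded in the truth log;
    rerunning with the same seed reproduces documents and log exactly.
    """
    rng = random.Random(seed)
    out = [d.copy() for d in docs]
    log = TruthLog()

    crosswalk_terms: dict[str, list[str]] = {}
    if crosswalk is not None:
        for e in crosswalk.entries:
            crosswalk_terms.setdefault(e.canonical_class, []).append(e.source_term)

    for spec in defects:
        if spec.mode == "version_skew":
            for doc in out:
                if rng.random() < spec.rate:
                    before = doc.schema_version
                    major, minor, patch = (int(x) for x in before.split("."))
                    doc.schema_version = f"{major}.{minor}.{patch + 1}"
                    log.entries.append(
                        TruthLogEntry("<document>", "version_skew", before, doc.schema_version)
                    )
            continue

        for doc in out:
            for obj in doc.objects:
                if rng.random() >= spec.rate:
                    continue
                entry = _inject(rng, schema, crosswalk_terms, obj, spec.mode)
                if entry is not None:
                    log.entries.append(entry)
    return out, log


def _inject(
    rng: random.Random,
    schema: Schema,
    crosswalk_terms: dict[str, list[str]],
    obj: AnnotationObject,
    mode: str,
) -> TruthLogEntry | None:
    cls = schema.class_by_name(obj.class_term)
    if cls is None:  # already corrupted by an earlier mode
        return None

    if mode == "synonym_swap":
        variants = _synonym_variants(schema, cls.name, crosswalk_terms)
        if not variants:
            return None
        before = obj.class_term
        obj.class_term = variants[rng.randrange(len(variants))]
        return TruthLogEntry(obj.id, mode, before, obj.class_term)

    if mode == "misspell":
        before = obj.class_term
        # the edit must not land on another valid term (e.g. a trailing "s"
        # would plural-fold back to the class), or detection would be silent
        for _ in range(100):
            cand = _misspell(rng, before)
            if not schema.resolve_class_term(cand)[0]:
                obj.class_term = cand
                return TruthLogEntry(obj.id, mode, before, obj.class_term)
        return None

    if mode == "separator_noise":
        before = obj.class_term
        style = rng.choice((", ", " | ", ",", "  "))
        obj.class_term = before.replace("_", style) + rng.choice((",", " |", ", "))
        return TruthLogEntry(obj.id, mode, before, obj.class_term)

    if mode == "wrong_home":
        foreign = [
            p for c, p in schema.iter_properties()
            if c.name != cls.name and p.ptype is not PropertyType.SPATIAL_POINT
        ]
        if not foreign:
            return None
        p = foreign[rng.randrange(len(foreign))]
        obj.properties[p.name] = _random_value(rng, p, schema)
        return TruthLogEntry(obj.id, mode, "", p.name)

    if mode == "bad_enum":
        enum_props = [p for p in cls.properties if p.ptype is PropertyType.ENUMERATION]
        if not enum_props:
            return None
        p = enum_props[rng.randrange(len(enum_props))]
        before = str(obj.properties.get(p.name, ""))
        obj.properties[p.name] = "definitely_" + rng.choice(("maybe", "not", "so"))
        return TruthLogEntry(obj.id, mode, before, str(obj.properties[p.name]))

    if mode == "missing_required":
        required = [p for p in cls.properties if p.required and p.name in obj.properties]
        if not required:
            return None
        p = required[rng.randrange(len(required))]
        before = str(obj.properties.pop(p.name))
        return TruthLogEntry(obj.id, mode, before, "")

    raise ValueError(f"unknown defect mode {mode!r}")


# ---------------------------------------------------------------------------
# schema mutation (for compatibility stress-testing)
# ---------------------------------------------------------------------------

ADDITION_MUTATIONS = ("add_class", "add_optional_property", "add_enum_value")
BREAKING_MUTATIONS = (
    "remove_class",
    "remove_property",
    "change_type",
    "remove_enum_value",
    "tighten_required",
    "add_required_property",
)

_SCALAR_TYPES = (
    PropertyType.INTEGER,
    PropertyType.FLOAT,
    PropertyType.STRING,
    PropertyType.BOOLEAN,
)


def _bump(version: str, breaking: bool) -> str:
    major, minor, _ = (int(x) for x in version.split("."))
    return f"{major + 1}.0.0" if breaking else f"{major}.{minor + 1}.0"


def _rebuild(schema: Schema, classes, enums, breaking: bool) -> Schema:
    return Schema(
        version=_bump(schema.version, breaking),
        classes=tuple(classes),
        enums=tuple(enums),
        extensions=schema.extensions,
    )


def mutate_schema(schema: Schema, seed: int) -> tuple[Schema, str, str]:
    """Apply one random structural mutation; returns (mutated, kind, op).

    ``kind`` is the ground truth for compatibility checkers: "addition"
    mutations (new class, new optional property, appended enum value) never
    break old documents; "breaking" mutations (removals, type changes, enum
    value removals, requiredness tightening, new required property) do.
    """
    rng = random.Random(seed)
    op = rng.choice(ADDITION_MUTATIONS + BREAKING_MUTATIONS)
    breaking = op in BREAKING_MUTATIONS
    classes = list(schema.classes)
    enums = list(schema.enums)
    fresh = f"x_{op}_{rng.randint(0, 10**6)}"

    if op == "add_class":
        classes.append(
            SchemaClass(
                name=f"cls_{fresh}",
                category=rng.choice(list(CategoryTag)),
                properties=(PropertySpec(f"p_{fresh}", rng.choice(_SCALAR_TYPES)),),
            )
        )
    elif op == "add_optional_property":
        i = rng.randrange(len(classes))
        c = classes[i]
        classes[i] = SchemaClass(
            c.name, c.category,
            c.properties + (PropertySpec(f"p_{fresh}", rng.choice(_SCALAR_TYPES)),),
            c.synonyms, c.parent,
        )
    elif op == "add_enum_value":
        i = rng.randrange(len(enums))
        e = enums[i]
        next_code = max(v.code for v in e.values) + 1
        enums[i] = EnumSpec(
            e.name, e.values + (EnumValue(f"v_{fresh}", next_code),), e.extensible
        )
    elif op == "remove_class":
        parents = {c.parent for c in classes if c.parent}
        removable = [c for c in classes if c.name not in parents]
        victim = removable[rng.randrange(len(removable))]
        classes = [c for c in classes if c.name != victim.name]
    elif op == "remove_property":
        owners = [i for i, c in enumerate(classes) if c.properties]
        i = owners[rng.randrange(len(owners))]
        c = classes[i]
        j = rng.randrange(len(c.properties))
        classes[i] = SchemaClass(
            c.name, c.category,
            c.properties[:j] + c.properties[j + 1 :], c.synonyms, c.parent,
        )
    elif op == "change_type":
        candidates = [
            (i, j)
            for i, c in enumerate(classes)
            for j, p in enumerate(c.properties)
            if p.ptype in _SCALAR_TYPES
        ]
        i, j = candidates[rng.randrange(len(candidates))]
        c = classes[i]
        p = c.properties[j]
        new_type = rng.choice([t for t in _SCALAR_TYPES if t is not p.ptype])
        props = list(c.properties)
        props[j] = PropertySpec(p.name, new_type, "", p.required, p.description)
        classes[i] = SchemaClass(c.name, c.category, tuple(props), c.synonyms, c.parent)
    elif op == "remove_enum_value":
        candidates = [i for i, e in enumerate(enums) if len(e.values) > 1]
        i = candidates[rng.randrange(len(candidates))]
        e = enums[i]
        j = rng.randrange(len(e.values))
        enums[i] = EnumSpec(e.name, e.values[:j] + e.values[j + 1 :], e.extensible)
    elif op == "tighten_required":
        candidates = [
            (i, j)
            for i, c in enumerate(classes)
            for j, p in enumerate(c.properties)
            if not p.required
        ]
        i, j = candidates[rng.randrange(len(candidates))]
        c = classes[i]
        p = c.properties[j]
        props = list(c.properties)
        props[j] = PropertySpec(p.name, p.ptype, p.enum_ref, True, p.description)
        classes[i] = SchemaClass(c.name, c.category, tuple(props), c.synonyms, c.parent)
    elif op == "add_required_property":
        i = rng.randrange(len(classes))
        c = classes[i]
        classes[i] = SchemaClass(
            c.name, c.category,
            c.properties
            + (PropertySpec(f"p_{fresh}", rng.choice(_SCALAR_TYPES), required=True),),
            c.synonyms, c.parent,
        )
    else:  # pragma: no cover
        raise AssertionError(op)

    kind = "breaking" if breaking else "addition"
    return _rebuild(schema, classes, enums, breaking), kind, op


# ---------------------------------------------------------------------------
# printed crosswalk and dataset tree
# ---------------------------------------------------------------------------

def table1_fixture() -> str:
    """The published study-term crosswalk, verbatim, as CSV.

    One row per canonical annotation, one column per source study; "NA"
    marks a study that does not annotate the entity.
    """
    rows = [
        ["Annotations", "Kasthuri et al. 2015", "Witvliet et al. 2020", "Hemibrain",
         "IARPA MICrONS Minnie", "H01", "Nguyen & Thomas, et al. 2022", "Prasad et al. 2020"],
        ["Cell Body", "Cell Body", "Soma", "Soma", "Soma", "Cell body", "Soma", "Cell body"],
        ["Region of Interest", "Cylinder", "Module", "Brain Region", "Layer", "Layer",
         "Region of Interest", "Cortex, Striatum, Thalamus, and Zona Incerta"],
        ["Neuron", "Neuron, Neuronal somata", "Neuron", "Neuron", "Neuron", "Neuron",
         "Neuron", "NA"],
        ["Bouton", "Bouton", "Passant boutons", "NA", "NA", "NA", "Bouton", "NA"],
        ["Interneurons", "Putative interneurons", "Interneurons", "NA", "NA", "NA",
         "Molecular layer interneurons", "NA"],
        ["Synapse", "Synapse", "Synapse", "Synapse", "Putative synapses", "Synapse",
         "Synapse", "Synapse"],
        ["Synaptic Cleft", "NA", "NA", "NA", "Cleft", "Clefts", "Synaptic Clefts",
         "Synaptic Cleft"],
        ["Spine Apparatus", "Spine Apparatus", "NA", "NA", "NA", "NA", "NA", "NA"],
    ]
    import csv as _csv
    import io as _io

    buf = _io.StringIO()
    w = _csv.writer(buf, lineterminator="\n")
    w.writerows(rows)
    return buf.getvalue()


def generate_tree(seed: int = 0) -> DatasetTree:
    """A small fully-populated 4-level dataset tree."""
    rng = random.Random(seed)
    tree = DatasetTree()

    def rec(name: str, level: HierarchyLevel) -> HierarchyRecord:
        return HierarchyRecord(
            name=name,
            level=level,
            title=name.replace("_", " ").title(),
            description=f"Synthetic {level.value} record for offline testing.",
            grant_number=f"GR-{rng.randint(10000, 99999)}",
            publications=[f"doi:10.0000/synthetic.{rng.randint(1000, 9999)}"],
            statistics={"size_tb": round(rng.uniform(0.1, 900.0), 1)},
        )

    for proj in ("microns", "h01"):
        ppath = add_record(tree, "", rec(proj, HierarchyLevel.PROJECT))
        for coll in ("minnie", "pinky"):
            cpath = add_record(tree, ppath, rec(coll, HierarchyLevel.COLLECTION))
            epath = add_record(tree, cpath, rec("em", HierarchyLevel.EXPERIMENT))
            for chan in ("image", "segmentation"):
                add_record(tree, epath, rec(chan, HierarchyLevel.CHANNEL))
    return tree
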