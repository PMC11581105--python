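"""Schema diffing, backward-compatibility verdicts and document migration.

A new schema version is backward compatible when every document valid under
the old version stays valid under the new one.  Operationally that means
additions never block (new classes, new *optional* properties, appended enum
values), while removals, type changes, enum value removals and any tightening
of requiredness break compatibility.  The verdict derives only from the
structural diff, and migration refuses to cross an incompatible diff (no
lossy migration).

A class rename is modeled as remove+add — breaking — unless the new class
lists the old name among its synonyms, in which case the existing synonym
machinery carries old documents across.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .documents import AnnotationDocument
from .schema_core import Schema, term_key


@dataclass
class SchemaDiff:
    added_classes: list[str] = field(default_factory=list)
    removed_classes: list[str] = field(default_factory=list)
    added_properties: list[tuple[str, str]] = field(default_factory=list)
    removed_properties: list[tuple[str, str]] = field(default_factory=list)
    type_changes: list[tuple[str, str, str, str]] = field(default_factory=list)
    enum_added_values: list[tuple[str, str]] = field(default_factory=list)
    enum_removed_values: list[tuple[str, str]] = field(default_factory=list)
    required_tightened: list[tuple[str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not any(
            getattr(self, f.name) for f in self.__dataclass_fields__.values()  # type: ignore[attr-defined]
        )

    def to_json(self) -> dict:
        return {
            "added_classes": self.added_classes,
            "removed_classes": self.removed_classes,
            "added_properties": [list(t) for t in self.added_properties],
            "removed_properties": [list(t) for t in self.removed_properties],
            "type_changes": [list(t) for t in self.type_changes],
            "enum_added_values": [list(t) for t in self.enum_added_values],
            "enum_removed_values": [list(t) for t in self.enum_removed_values],
            "required_tightened": [list(t) for t in self.required_tightened],
        }


def _class_mapping(old: Schema, new: Schema) -> dict[str, str]:
    """Map each old class to its counterpart in *new* (name match, else a new
    class that lists the old name as a synonym)."""
    mapping: dict[str, str] = {}
    new_names = {c.name for c in new.classes}
    for oc in old.classes:
        if oc.name in new_names:
            mapping[oc.name] = oc.name
            continue
        k = term_key(oc.name)
        for nc in new.classes:
            if any(term_key(s) == k for s in nc.synonyms):
                mapping[oc.name] = nc.name
                break
    return mapping


def diff_schemas(old: Schema, new: Schema) -> SchemaDiff:
    """Exhaustive structural diff; diff(s, s) is empty in every field and
    diff(a, b).added mirrors diff(b, a).removed."""
    d = SchemaDiff()
    fwd = _class_mapping(old, new)
    covered_new = set(fwd.values())

    d.removed_classes = sorted(c.name for c in old.classes if c.name not in fwd)
    d.added_classes = sorted(c.name for c in new.classes if c.name not in covered_new)

    for oc in old.classes:
        target = fwd.get(oc.name)
        nc = new.class_by_name(target) if target else None
        old_props = {p.name: p for p in oc.properties}
        new_props = {p.name: p for p in nc.properties} if nc else {}
        for pname, op in sorted(old_props.items()):
            np = new_props.get(pname)
            if np is None:
                d.removed_properties.append((oc.name, pname))
                continue
            if np.ptype is not op.ptype or np.enum_ref != op.enum_ref:
                d.type_changes.append(
                    (oc.name, pname, op.ptype.value, np.ptype.value)
                )
            if np.required and not op.required:
                d.required_tightened.append((oc.name, pname))
        for pname, np in sorted(new_props.items()):
            if pname not in old_props:
                d.added_properties.append((target or oc.name, pname))
                # a newly added *required* property also tightens requirements:
                # old documents cannot carry it
                if np.required:
                    d.required_tightened.append((target or oc.name, pname))

    for nc in new.classes:
        if nc.name not in covered_new:
            for p in nc.properties:
                d.added_properties.append((nc.name, p.name))
                if p.required:
                    # required property of a brand-new class never affects old
                    # documents; do not tighten
                    pass

    old_enums = {e.name: e for e in old.enums}
    new_enums = {e.name: e for e in new.enums}
    for ename, oe in sorted(old_enums.items()):
        ne = new_enums.get(ename)
        if ne is None:
            d.enum_removed_values.extend((ename, v.name) for v in oe.values)
            continue
        ov = {v.name for v in oe.values}
        nv = {v.name for v in ne.values}
        d.enum_removed_values.extend((ename, v) for v in sorted(ov - nv))
        d.enum_added_values.extend((ename, v) for v in sorted(nv - ov))
    for ename, ne in sorted(new_enums.items()):
        if ename not in old_enums:
            d.enum_added_values.extend((ename, v.name) for v in ne.values)
    return d


@dataclass
class CompatReport:
    compatible: bool
    blocking: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {"compatible": self.compatible, "blocking": self.blocking, "notes": self.notes}


def is_backward_compatible(old: Schema, new: Schema) -> CompatReport:
    """Compatible iff the diff contains no removals, no type changes, no enum
    value removals and no requiredness tightening; additions never block."""
    d = diff_schemas(old, new)
    blocking: list[str] = []
    blocking += [f"removed class {c!r}" for c in d.removed_classes]
    blocking += [f"removed property {c}.{p}" for c, p in d.removed_properties]
    blocking += [
        f"type change {c}.{p}: {a} -> {b}" for c, p, a, b in d.type_changes
    ]
    blocking += [f"removed enum value {e}.{v}" for e, v in d.enum_removed_values]
    blocking += [f"required tightened {c}.{p}" for c, p in d.required_tightened]
    notes = []
    if d.added_classes:
        notes.append("added classes: " + ", ".join(d.added_classes))
    if d.added_properties:
        notes.append(
            "added properties: " + ", ".join(f"{c}.{p}" for c, p in d.added_properties)
        )
    if d.enum_added_values:
        notes.append(
            "added enum values: " + ", ".join(f"{e}.{v}" for e, v in d.enum_added_values)
        )
    return CompatReport(compatible=not blocking, blocking=blocking, notes=notes)


class MigrationError(ValueError):
    """Refusal to migrate across an incompatible schema change."""


def migrate_document(
    doc: AnnotationDocument, old: Schema, new: Schema
) -> AnnotationDocument:
    """Migrate a document valid under *old* to *new*'s version.

    Only the schema_version changes (and, for synonym-mediated class renames,
    nothing: the synonym machinery keeps old class terms valid).  Refuses when
    the schemas are not backward compatible.
    """
    verdict = is_backward_compatible(old, new)
    if not verdict.compatible:
        raise MigrationError(
            "cannot migrate across incompatible change(s): " + "; ".join(verdict.blocking)
        )
    out = doc.copy()
    out.schema_version = new.version
    return out
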