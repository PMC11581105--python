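"""Validate annotation documents and bundles against a schema.

Every check emits a :class:`ValidationIssue` with a closed issue code and a
locatable path (object id, optionally + property); a report is ``ok`` iff it
carries zero error-severity issues.  Synonym class terms ("cell body" for
``soma``) validate with a warning recommending the canonical form —
normalization, not validation, is the fix path for legacy terms.
Cross-version validation is deliberately an error (``VERSION_MISMATCH``):
documents are migrated first, then validated.
"""

from __future__ import annotations

from typing import Any, Sequence

from .documents import AnnotationDocument, AnnotationObject
from .report import IssueCode, Severity, ValidationIssue, ValidationReport
from .schema_core import BoundSpatialPoint, PropertyType, Schema, SchemaError


def check_anchor(
    anchor: BoundSpatialPoint,
    extent: tuple[int, int, int] | None = None,
    path: str = "anchor",
) -> ValidationIssue | None:
    """Check a spatial anchor against an optional volume extent.

    Coordinates must be non-negative and, when the extent is known, satisfy
    0 <= c < extent component (half-open bounds).  Returns None when ok.
    """
    for axis, c in zip("xyz", anchor.position):
        if c < 0:
            return ValidationIssue(
                IssueCode.BAD_ANCHOR, Severity.ERROR, path,
                f"negative {axis} coordinate {c}",
            )
        if extent is not None:
            bound = extent["xyz".index(axis)]
            if not c < bound:
                return ValidationIssue(
                    IssueCode.BAD_ANCHOR, Severity.ERROR, path,
                    f"{axis} coordinate {c} outside half-open extent [0, {bound})",
                )
    return None


def _value_conforms(value: Any, ptype: PropertyType) -> bool:
    if ptype is PropertyType.BOOLEAN:
        return isinstance(value, bool)
    if ptype is PropertyType.INTEGER:
        if isinstance(value, bool):
            return False
        if isinstance(value, int):
            return True
        # integral floats (3.0) are a common serialization artifact
        return isinstance(value, float) and value.is_integer()
    if ptype is PropertyType.FLOAT:
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if ptype is PropertyType.STRING:
        return isinstance(value, str)
    if ptype is PropertyType.IDENTIFIER:
        return isinstance(value, str) or (isinstance(value, int) and not isinstance(value, bool))
    if ptype is PropertyType.ENUMERATION:
        return isinstance(value, (str, int)) and not isinstance(value, bool)
    if ptype is PropertyType.SPATIAL_POINT:
        try:
            BoundSpatialPoint.from_json(value)
        except SchemaError:
            return False
        return True
    return False


def _validate_object(
    schema: Schema,
    obj: AnnotationObject,
    extent: tuple[int, int, int] | None,
    require_anchor: bool,
    issues: list[ValidationIssue],
) -> None:
    cls_name, how = schema.resolve_class_term(obj.class_term)
    if not cls_name:
        issues.append(
            ValidationIssue(
                IssueCode.UNKNOWN_CLASS, Severity.ERROR, obj.id,
                f"class term {obj.class_term!r} matches no schema class or synonym",
            )
        )
    elif how == "synonym" or obj.class_term != cls_name:
        issues.append(
            ValidationIssue(
                IssueCode.UNKNOWN_CLASS, Severity.WARNING, obj.id,
                f"class term {obj.class_term!r} is not canonical; use {cls_name!r} "
                f"(normalize_document rewrites it)",
            )
        )
    cls = schema.class_by_name(cls_name) if cls_name else None

    for pname, value in obj.properties.items():
        path = f"{obj.id}.{pname}"
        spec = schema.property_spec(pname)
        if spec is None:
            issues.append(
                ValidationIssue(
                    IssueCode.UNKNOWN_PROPERTY, Severity.ERROR, path,
                    f"property {pname!r} does not exist in schema {schema.version}",
                )
            )
            continue
        home = schema.property_home(pname)
        if cls is not None and home != cls.name:
            issues.append(
                ValidationIssue(
                    IssueCode.WRONG_HOME, Severity.ERROR, path,
                    f"property {pname!r} is housed under class {home!r}, "
                    f"not {cls.name!r} (single-home rule)",
                )
            )
            continue
        if not _value_conforms(value, spec.ptype):
            issues.append(
                ValidationIssue(
                    IssueCode.TYPE_MISMATCH, Severity.ERROR, path,
                    f"value {value!r} does not conform to type {spec.ptype.value}",
                )
            )
            continue
        if spec.ptype is PropertyType.ENUMERATION:
            enum = schema.enum_by_name(spec.enum_ref)
            if enum is not None and not enum.is_member(value):
                issues.append(
                    ValidationIssue(
                        IssueCode.ENUM_VIOLATION, Severity.ERROR, path,
                        f"value {value!r} is not a member of enum {enum.name!r} "
                        + ("(extensible: prefix user values with 'x-')"
                           if enum.extensible else "(closed enum)"),
                    )
                )
            elif (
                enum is not None
                and isinstance(value, str)
                and value.startswith("x-")
            ):
                issues.append(
                    ValidationIssue(
                        IssueCode.ENUM_VIOLATION, Severity.WARNING, path,
                        f"extension value {value!r} on enum {enum.name!r} "
                        f"is outside the codified value set",
                    )
                )

    if cls is not None:
        for p in cls.properties:
            if p.required and p.name not in obj.properties:
                issues.append(
                    ValidationIssue(
                        IssueCode.MISSING_REQUIRED, Severity.ERROR, f"{obj.id}.{p.name}",
                        f"required property {p.name!r} of class {cls.name!r} is missing",
                    )
                )

    if obj.anchor is not None:
        issue = check_anchor(obj.anchor, extent, path=f"{obj.id}.anchor")
        if issue is not None:
            issues.append(issue)
    elif require_anchor:
        issues.append(
            ValidationIssue(
                IssueCode.BAD_ANCHOR, Severity.ERROR, f"{obj.id}.anchor",
                "spatial anchor required by configuration but absent",
            )
        )


def validate_document(
    schema: Schema,
    doc: AnnotationDocument,
    extent: tuple[int, int, int] | None = None,
    require_anchor: bool = False,
) -> ValidationReport:
    """Validate one document against *schema*.

    Checks, per object: class term resolves; properties exist, sit in their
    home class, conform to their declared type and enum membership; required
    properties are present; ids are unique; anchors are well-formed.  The
    document's declared schema_version must equal the schema's version.
    """
    issues: list[ValidationIssue] = []
    if doc.schema_version != schema.version:
        issues.append(
            ValidationIssue(
                IssueCode.VERSION_MISMATCH, Severity.ERROR, "schema_version",
                f"document declares {doc.schema_version!r} but schema is "
                f"{schema.version!r}; migrate before validating",
            )
        )
    seen: set[str] = set()
    for obj in doc.objects:
        if obj.id in seen:
            issues.append(
                ValidationIssue(
                    IssueCode.DUPLICATE_ID, Severity.ERROR, obj.id,
                    f"object id {obj.id!r} is not unique within the document",
                )
            )
        seen.add(obj.id)
        _validate_object(schema, obj, extent, require_anchor, issues)
    return ValidationReport(issues=issues)


def validate_bundle(
    schema: Schema,
    docs: Sequence[AnnotationDocument],
    extent: tuple[int, int, int] | None = None,
) -> ValidationReport:
    """Validate a bundle: all single-document checks plus cross-document
    version consistency (the schema version must be consistent throughout all
    representation) and cross-document id collisions (warnings)."""
    if not docs:
        raise ValueError("bundle must contain at least one document")
    report = ValidationReport()
    versions: dict[str, int] = {}
    ids_seen: dict[str, int] = {}
    for i, doc in enumerate(docs):
        versions.setdefault(doc.schema_version, i)
        sub = validate_document(schema, doc, extent=extent)
        for issue in sub.issues:
            report.issues.append(
                ValidationIssue(issue.code, issue.severity, f"doc[{i}].{issue.path}", issue.message)
            )
        for obj in doc.objects:
            if obj.id in ids_seen and ids_seen[obj.id] != i:
                report.issues.append(
                    ValidationIssue(
                        IssueCode.DUPLICATE_ID, Severity.WARNING, f"doc[{i}].{obj.id}",
                        f"object id {obj.id!r} also appears in doc[{ids_seen[obj.id]}]",
                    )
                )
            ids_seen.setdefault(obj.id, i)
    if len(versions) > 1:
        listed = ", ".join(sorted(versions))
        report.issues.append(
            ValidationIssue(
                IssueCode.VERSION_MISMATCH, Severity.ERROR, "bundle",
                f"bundle mixes schema versions: {listed}",
            )
        )
    return report
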