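"""Annotation documents: bundles of annotation objects claiming a schema version.

The JSON dialect has top-level keys ``schema_version``, ``dataset_path``,
``objects`` and ``extensions``.  Each object carries an id, a class term
(canonical name, synonym, or a study-specific string), a property map and an
optional spatial anchor binding it to a segmentation segment.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any

from .schema_core import BoundSpatialPoint, SchemaError


class DocumentError(ValueError):
    """The document text cannot be parsed (distinct from validation issues)."""


@dataclass
class AnnotationObject:
    id: str
    class_term: str
    properties: dict[str, Any] = field(default_factory=dict)
    anchor: BoundSpatialPoint | None = None

    def to_json(self) -> dict[str, Any]:
        return {
            "id": self.id,
            "class": self.class_term,
            "properties": dict(self.properties),
            "anchor": self.anchor.to_json() if self.anchor is not None else None,
        }


@dataclass
class AnnotationDocument:
    schema_version: str
    dataset_path: str = ""
    objects: list[AnnotationObject] = field(default_factory=list)
    extensions: dict[str, Any] = field(default_factory=dict)

    def copy(self) -> "AnnotationDocument":
        return copy.deepcopy(self)

    def to_json(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "dataset_path": self.dataset_path,
            "objects": [o.to_json() for o in self.objects],
            "extensions": dict(self.extensions),
        }


def serialize_document(doc: AnnotationDocument) -> str:
    """Deterministic serialization (sorted keys in objects, list order kept)."""
    return json.dumps(doc.to_json(), indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def load_document(text: str) -> AnnotationDocument:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentError(f"malformed annotation document: {exc}") from exc
    if not isinstance(obj, dict) or "schema_version" not in obj:
        raise DocumentError("annotation document must be an object with 'schema_version'")
    objects = []
    for i, o in enumerate(obj.get("objects", [])):
        if not isinstance(o, dict) or "id" not in o or "class" not in o:
            raise DocumentError(f"objects[{i}]: each object needs 'id' and 'class'")
        anchor = None
        if o.get("anchor") is not None:
            try:
                anchor = BoundSpatialPoint.from_json(o["anchor"])
            except SchemaError as exc:
                raise DocumentError(f"objects[{i}].anchor: {exc}") from exc
        objects.append(
            AnnotationObject(
                id=str(o["id"]),
                class_term=str(o["class"]),
                properties=dict(o.get("properties", {})),
                anchor=anchor,
            )
        )
    return AnnotationDocument(
        schema_version=str(obj["schema_version"]),
        dataset_path=str(obj.get("dataset_path", "")),
        objects=objects,
        extensions=dict(obj.get("extensions", {})),
    )
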