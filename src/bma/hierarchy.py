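"""Four-level experimental-metadata hierarchy.

Volumetric datasets are subdivided into projects, collections, experiments
and channels, in that strict order; each record carries a title, description,
grant number, publication list and free-form statistics.  Title and
description are required for a record to validate; grant number and
publications are recommended (warnings only), since many historical datasets
lack them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator

from .report import IssueCode, Severity, ValidationIssue

_NAME_RE = re.compile(r"^[a-z0-9_\-]+$")


class HierarchyError(ValueError):
    """Structural violation of the project/collection/experiment/channel order."""


class HierarchyLevel(str, Enum):
    PROJECT = "project"
    COLLECTION = "collection"
    EXPERIMENT = "experiment"
    CHANNEL = "channel"

    @property
    def depth(self) -> int:
        return _LEVEL_ORDER.index(self)

    def child_level(self) -> "HierarchyLevel | None":
        i = self.depth + 1
        return _LEVEL_ORDER[i] if i < len(_LEVEL_ORDER) else None


_LEVEL_ORDER = [
    HierarchyLevel.PROJECT,
    HierarchyLevel.COLLECTION,
    HierarchyLevel.EXPERIMENT,
    HierarchyLevel.CHANNEL,
]


@dataclass
class HierarchyRecord:
    """One dataset-hierarchy entity with its descriptive metadata."""

    name: str
    level: HierarchyLevel
    title: str = ""
    description: str = ""
    grant_number: str = ""
    publications: list[str] = field(default_factory=list)
    statistics: dict[str, float] = field(default_factory=dict)
    children: list["HierarchyRecord"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise HierarchyError(
                f"record name {self.name!r} must match [a-z0-9_-]+ (URL-safe paths)"
            )

    def to_json(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "level": self.level.value,
            "title": self.title,
            "description": self.description,
            "grant_number": self.grant_number,
            "publications": list(self.publications),
            "statistics": dict(self.statistics),
            "children": [c.to_json() for c in self.children],
        }

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "HierarchyRecord":
        return cls(
            name=obj["name"],
            level=HierarchyLevel(obj["level"]),
            title=obj.get("title", ""),
            description=obj.get("description", ""),
            grant_number=obj.get("grant_number", ""),
            publications=list(obj.get("publications", [])),
            statistics=dict(obj.get("statistics", {})),
            children=[cls.from_json(c) for c in obj.get("children", [])],
        )


@dataclass
class DatasetTree:
    roots: list[HierarchyRecord] = field(default_factory=list)

    def to_json(self) -> dict[str, Any]:
        return {"roots": [r.to_json() for r in self.roots]}

    def serialize(self) -> str:
        return json.dumps(self.to_json(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def load(cls, text: str) -> "DatasetTree":
        doc = json.loads(text)
        tree = cls(roots=[HierarchyRecord.from_json(r) for r in doc.get("roots", [])])
        for rec, path in tree.walk():
            _check_structure(rec, path)
        return tree

    def walk(self) -> Iterator[tuple[HierarchyRecord, str]]:
        def rec(node: HierarchyRecord, prefix: str) -> Iterator[tuple[HierarchyRecord, str]]:
            path = f"{prefix}/{node.name}" if prefix else node.name
            yield node, path
            for child in node.children:
                yield from rec(child, path)

        for root in self.roots:
            yield from rec(root, "")


def _check_structure(record: HierarchyRecord, path: str) -> None:
    expected_depth = path.count("/")
    if record.level.depth != expected_depth:
        raise HierarchyError(
            f"{path}: level {record.level.value!r} at depth {expected_depth} "
            f"violates project/collection/experiment/channel order"
        )
    names = [c.name for c in record.children]
    if len(set(names)) != len(names):
        raise HierarchyError(f"{path}: duplicate sibling names among children")


def resolve_path(tree: DatasetTree, path: str) -> HierarchyRecord | None:
    """Return the record at the slash-path, or None (empty path is no record)."""
    if not path:
        return None
    parts = path.split("/")
    nodes = tree.roots
    node: HierarchyRecord | None = None
    for part in parts:
        node = next((n for n in nodes if n.name == part), None)
        if node is None:
            return None
        nodes = node.children
    return node


def add_record(tree: DatasetTree, parent_path: str, record: HierarchyRecord) -> str:
    """Insert *record* under *parent_path* (empty for a project root).

    The record's level must be exactly one step below its parent's; sibling
    names must be unique.  Returns the full slash-path of the new record.
    """
    if parent_path:
        parent = resolve_path(tree, parent_path)
        if parent is None:
            raise HierarchyError(f"parent path {parent_path!r} does not resolve")
        expected = parent.level.child_level()
        if expected is None:
            raise HierarchyError(f"{parent_path!r} is a channel and cannot have children")
        siblings = parent.children
    else:
        expected = HierarchyLevel.PROJECT
        siblings = tree.roots

    if record.level is not expected:
        raise HierarchyError(
            f"level violation: expected {expected.value!r} under "
            f"{parent_path or '<root>'!r}, got {record.level.value!r}"
        )
    if any(s.name == record.name for s in siblings):
        raise HierarchyError(f"duplicate sibling name {record.name!r} under {parent_path or '<root>'!r}")
    siblings.append(record)
    return f"{parent_path}/{record.name}" if parent_path else record.name


def validate_tree(tree: DatasetTree) -> list[ValidationIssue]:
    """One MISSING_REQUIRED error per missing title/description per record;
    warnings for absent grant number / publications."""
    issues: list[ValidationIssue] = []
    for rec, path in tree.walk():
        for fname in ("title", "description"):
            if not getattr(rec, fname).strip():
                issues.append(
                    ValidationIssue(
                        IssueCode.MISSING_REQUIRED,
                        Severity.ERROR,
                        f"{path}.{fname}",
                        f"{rec.level.value} record {path!r} lacks a {fname}",
                    )
                )
        if not rec.grant_number.strip():
            issues.append(
                ValidationIssue(
                    IssueCode.MISSING_REQUIRED,
                    Severity.WARNING,
                    f"{path}.grant_number",
                    f"{path!r}: grant number is recommended",
                )
            )
        if not rec.publications:
            issues.append(
                ValidationIssue(
                    IssueCode.MISSING_REQUIRED,
                    Severity.WARNING,
                    f"{path}.publications",
                    f"{path!r}: publication information is recommended",
                )
            )
    return issues
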