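"""Machine-readable issue reports shared by the validators."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum


class IssueCode(str, Enum):
    UNKNOWN_CLASS = "UNKNOWN_CLASS"
    UNKNOWN_PROPERTY = "UNKNOWN_PROPERTY"
    WRONG_HOME = "WRONG_HOME"
    TYPE_MISMATCH = "TYPE_MISMATCH"
    ENUM_VIOLATION = "ENUM_VIOLATION"
    MISSING_REQUIRED = "MISSING_REQUIRED"
    VERSION_MISMATCH = "VERSION_MISMATCH"
    DUPLICATE_ID = "DUPLICATE_ID"
    BAD_ANCHOR = "BAD_ANCHOR"


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class ValidationIssue:
    """One finding, locatable via ``path`` (object id, optionally + property)."""

    code: IssueCode
    severity: Severity
    path: str
    message: str

    def to_json(self) -> dict:
        return {
            "code": self.code.value,
            "severity": self.severity.value,
            "path": self.path,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """True iff the report carries zero error-severity issues."""
        return not any(i.severity is Severity.ERROR for i in self.issues)

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(i.code.value for i in self.issues))

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.ERROR]

    def by_code(self, code: IssueCode) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code is code]

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    def to_json(self) -> dict:
        return {
            "ok": self.ok,
            "counts": self.counts,
            "issues": [i.to_json() for i in self.issues],
        }
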