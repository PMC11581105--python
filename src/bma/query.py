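"""Separator-tolerant filter queries over annotation collections.

Hand-entered query lists mix commas, vertical bars and spaces as separators;
the tokenizer treats any run of them as one separator so that stylistic
choices never change a result set.  The grammar is a conjunction of clauses
joined by ``&``:

    class=synapse & has=spine_id & confidence in high,medium & apical=true

``class=X`` filters by (normalized) class, ``has=P`` by property presence,
``P=V`` by equality and ``P in A,B|C`` by membership.  Class terms in the
data are normalized before comparison, so objects annotated "Cell body"
match ``class=soma``.  Enumeration values compare by name or numeric code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Sequence

from .documents import AnnotationDocument, AnnotationObject
from .schema_core import PropertyType, Schema
from .vocabulary import CrosswalkTable, known_terms, normalize_term, suggest_terms

_SEP_RE = re.compile(r"[,\|\s]+")


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownQueryTermError(ValueError):
    """A query names a property absent from the schema; carries suggestions."""

    def __init__(self, term: str, suggestions: list[tuple[str, int]]):
        hint = (
            "; did you mean: " + ", ".join(t for t, _ in suggestions)
            if suggestions
            else ""
        )
        super().__init__(f"unknown property {term!r} in query{hint}")
        self.term = term
        self.suggestions = suggestions


def tokenize_list(text: str) -> list[str]:
    """Split on any run of commas, bars and whitespace; drop empty tokens;
    lowercase; preserve order."""
    return [t.lower() for t in _SEP_RE.split(text) if t]


@dataclass(frozen=True)
class Predicate:
    kind: str  # class_is | has_property | property_equals | property_in
    class_or_property: str
    values: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "has_property" and self.values:
            raise QuerySyntaxError("has_property takes no values")
        if self.kind == "property_equals" and len(self.values) != 1:
            raise QuerySyntaxError("property_equals takes exactly one value")
        if self.kind == "property_in" and not self.values:
            raise QuerySyntaxError("property_in needs at least one value")


@dataclass(frozen=True)
class QueryExpr:
    """A conjunction of predicates; the empty query matches everything."""

    predicates: tuple[Predicate, ...] = ()


def parse_query(text: str) -> QueryExpr:
    """Parse the clause grammar.  Raises :class:`QuerySyntaxError` with the
    offending position on malformed input."""
    if not text.strip():
        return QueryExpr()
    predicates: list[Predicate] = []
    pos = 0
    for raw in text.split("&"):
        clause = raw.strip()
        at = pos + (len(raw) - len(raw.lstrip()))
        pos += len(raw) + 1
        if not clause:
            raise QuerySyntaxError("empty clause", at)
        m = re.match(r"^(\S+)\s+in\s+(.+)$", clause)
        if m and "=" not in clause:
            values = tokenize_list(m.group(2))
            if not values:
                raise QuerySyntaxError("'in' clause with empty value list", at)
            predicates.append(Predicate("property_in", m.group(1).lower(), tuple(values)))
            continue
        if "=" not in clause:
            raise QuerySyntaxError(f"clause {clause!r} is not KEY=VALUE or 'P in LIST'", at)
        key, _, value = clause.partition("=")
        key, value = key.strip().lower(), value.strip()
        if not key or not value:
            raise QuerySyntaxError(f"clause {clause!r} has an empty side", at)
        if key == "class":
            tokens = tokenize_list(value)
            if len(tokens) != 1:
                raise QuerySyntaxError("class= takes exactly one class token", at)
            predicates.append(Predicate("class_is", tokens[0]))
        elif key == "has":
            tokens = tokenize_list(value)
            if len(tokens) != 1:
                raise QuerySyntaxError("has= takes exactly one property token", at)
            predicates.append(Predicate("has_property", tokens[0]))
        else:
            predicates.append(Predicate("property_equals", key, (value.lower(),)))
    return QueryExpr(tuple(predicates))


def _values_equal(raw: Any, wanted: str, schema: Schema, pname: str) -> bool:
    spec = schema.property_spec(pname)
    if isinstance(raw, bool):
        return wanted in (("true", "1") if raw else ("false", "0"))
    if spec is not None and spec.ptype is PropertyType.ENUMERATION:
        enum = schema.enum_by_name(spec.enum_ref)
        if enum is not None:
            # accept either the value name or its numeric code
            for v in enum.values:
                if (isinstance(raw, str) and raw.lower() == v.name.lower()) or raw == v.code:
                    return wanted.lower() in (v.name.lower(), str(v.code))
        return str(raw).lower() == wanted.lower()
    if isinstance(raw, (int, float)):
        try:
            return float(raw) == float(wanted)
        except ValueError:
            return False
    return str(raw).lower() == wanted.lower()


def _matches(
    obj: AnnotationObject,
    canonical_class: str,
    q: QueryExpr,
    schema: Schema,
) -> bool:
    for p in q.predicates:
        if p.kind == "class_is":
            if canonical_class != p.class_or_property:
                return False
        elif p.kind == "has_property":
            if p.class_or_property not in obj.properties:
                return False
        elif p.kind == "property_equals":
            if p.class_or_property not in obj.properties:
                return False
            if not _values_equal(
                obj.properties[p.class_or_property], p.values[0], schema, p.class_or_property
            ):
                return False
        elif p.kind == "property_in":
            if p.class_or_property not in obj.properties:
                return False
            raw = obj.properties[p.class_or_property]
            if not any(
                _values_equal(raw, w, schema, p.class_or_property) for w in p.values
            ):
                return False
    return True


def evaluate(
    q: QueryExpr,
    docs: Sequence[AnnotationDocument],
    schema: Schema,
    crosswalk: CrosswalkTable | None = None,
) -> set[str]:
    """Evaluate a query over documents; returns the set of matching object ids.

    Class terms are normalized before comparison (objects annotated with a
    synonym or crosswalk term match their canonical class), and so is the
    query's own ``class=`` token.  Unknown property names in the query raise
    :class:`UnknownQueryTermError` with nearest-term suggestions.
    """
    prop_names = {p.name for _, p in schema.iter_properties()}
    resolved: list[Predicate] = []
    for p in q.predicates:
        if p.kind == "class_is":
            res = normalize_term(schema, crosswalk, p.class_or_property)
            resolved.append(
                Predicate("class_is", res.canonical_class or p.class_or_property)
            )
        else:
            if p.class_or_property not in prop_names:
                raise UnknownQueryTermError(
                    p.class_or_property,
                    suggest_terms(sorted(prop_names), p.class_or_property, 2),
                )
            resolved.append(p)
    rq = QueryExpr(tuple(resolved))

    out: set[str] = set()
    for doc in docs:
        for obj in doc.objects:
            res = normalize_term(schema, crosswalk, obj.class_term)
            if _matches(obj, res.canonical_class, rq, schema):
                out.add(obj.id)
    return out
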