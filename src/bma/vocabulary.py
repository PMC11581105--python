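"""Controlled-vocabulary normalization via a study-term crosswalk.

Different studies annotate the same neuronal entity under different key
words ("cell body" vs "soma", "passant boutons" vs "bouton").  A crosswalk
table — one row per canonical class, one column per source study — maps the
study-specific terms onto the schema's canonical classes so that documents
from different datasets become comparable and queryable.

Matching is case-insensitive, trims surrounding whitespace, collapses
internal whitespace and folds a trailing plural "s".  Misspelled terms are
never auto-corrected: they are left untouched and reported, with ranked
edit-distance suggestions from the known vocabulary.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

import edlib

from .documents import AnnotationDocument
from .schema_core import Schema, term_key

DEFAULT_MAX_DISTANCE = 2


class CrosswalkError(ValueError):
    """Malformed or conflicting crosswalk table."""


@dataclass(frozen=True)
class CrosswalkEntry:
    source_term: str
    canonical_class: str
    source_study: str


@dataclass
class CrosswalkTable:
    """A function from source terms to canonical classes.

    The loader guarantees functionality: a (lowercased, trimmed) source term
    maps to exactly one canonical class across all studies.
    """

    entries: list[CrosswalkEntry] = field(default_factory=list)
    studies: list[str] = field(default_factory=list)
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def add(self, entry: CrosswalkEntry) -> None:
        key = term_key(entry.source_term)
        prev = self._index.get(key)
        if prev is not None and prev != entry.canonical_class:
            raise CrosswalkError(
                f"conflicting mapping: term {entry.source_term!r} maps to both "
                f"{prev!r} and {entry.canonical_class!r}"
            )
        self._index[key] = entry.canonical_class
        self.entries.append(entry)

    def lookup(self, term: str) -> str | None:
        key = term_key(term)
        hit = self._index.get(key)
        if hit is None and key.endswith("s") and len(key) > 1:
            hit = self._index.get(key[:-1])
        return hit

    def source_terms(self) -> list[str]:
        return [e.source_term for e in self.entries]


def _split_cell(cell: str) -> list[str]:
    """Split a multi-term cell on commas (and a leading 'and' on the last part)."""
    parts = [p.strip() for p in cell.split(",")]
    out = []
    for p in parts:
        p = re.sub(r"^and\s+", "", p, flags=re.IGNORECASE).strip()
        if p:
            out.append(p)
    return out


def load_crosswalk(table_text: str, schema: Schema) -> CrosswalkTable:
    """Load a crosswalk CSV/TSV.

    First column holds the canonical row label (resolved against the schema's
    class names and synonyms); the header row names the source studies.
    "NA" cells are skipped; multi-term cells split into one entry per term.
    """
    delimiter = "\t" if "\t" in table_text.splitlines()[0] else ","
    rows = list(csv.reader(io.StringIO(table_text), delimiter=delimiter))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise CrosswalkError("crosswalk needs a header row and at least one data row")
    header = rows[0]
    studies = [h.strip() for h in header[1:]]
    table = CrosswalkTable(studies=studies)
    for r, row in enumerate(rows[1:], start=2):
        label = row[0].strip()
        cls, _how = schema.resolve_class_term(label)
        if not cls:
            raise CrosswalkError(
                f"row {r}: label {label!r} matches no schema class or synonym"
            )
        # the row label itself is a valid source term for its class
        if table.lookup(label) is None:
            table.add(CrosswalkEntry(label, cls, source_study=""))
        for study, cell in zip(studies, row[1:]):
            cell = cell.strip()
            if not cell or cell.upper() == "NA":
                continue
            for term in _split_cell(cell):
                table.add(CrosswalkEntry(term, cls, source_study=study))
    return table


@dataclass(frozen=True)
class NormalizationResult:
    input_term: str
    canonical_class: str
    matched_via: str  # exact | synonym | crosswalk | none
    suggestions: tuple[tuple[str, int], ...] = ()


def known_terms(schema: Schema, crosswalk: CrosswalkTable | None = None) -> list[str]:
    """All terms the normalizer recognizes: class names, synonyms, crosswalk terms."""
    terms: dict[str, None] = {}
    for c in schema.classes:
        terms.setdefault(c.name, None)
        for s in c.synonyms:
            terms.setdefault(s, None)
    if crosswalk is not None:
        for t in crosswalk.source_terms():
            terms.setdefault(t, None)
    return list(terms)


def levenshtein(a: str, b: str) -> int:
    """Exact global edit distance (unit insert/delete/substitute costs)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def suggest_terms(
    vocab: list[str], term: str, max_distance: int = DEFAULT_MAX_DISTANCE
) -> list[tuple[str, int]]:
    """Known terms within edit distance <= max_distance of *term*, ranked by
    (distance, lexicographic); exact matches excluded.  Distances are computed
    on matching keys (case/whitespace-folded)."""
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    key = term_key(term)
    best: dict[str, tuple[int, str]] = {}
    for v in vocab:
        vk = term_key(v)
        if vk == key:
            continue
        d = levenshtein(key, vk)
        if d <= max_distance and (vk not in best or d < best[vk][0]):
            best[vk] = (d, v)
    ranked = sorted(((v, d) for d, v in best.values()), key=lambda t: (t[1], t[0].lower()))
    return ranked


def normalize_term(
    schema: Schema,
    crosswalk: CrosswalkTable | None,
    term: str,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> NormalizationResult:
    """Resolve a term to its canonical class.

    Matching order: exact canonical class name, then schema synonym, then
    crosswalk entry (all case-insensitive, whitespace-trimmed).  On no match
    the result carries ranked edit-distance suggestions instead.
    """
    cls, how = schema.resolve_class_term(term)
    if cls:
        return NormalizationResult(term, cls, how)
    if crosswalk is not None:
        hit = crosswalk.lookup(term)
        if hit is not None:
            return NormalizationResult(term, hit, "crosswalk")
    sugg = suggest_terms(known_terms(schema, crosswalk), term, max_distance)
    return NormalizationResult(term, "", "none", tuple(sugg))


@dataclass(frozen=True)
class ChangeLogEntry:
    path: str
    old_term: str
    new_term: str
    matched_via: str


def normalize_document(
    schema: Schema,
    crosswalk: CrosswalkTable | None,
    doc: AnnotationDocument,
) -> tuple[AnnotationDocument, list[ChangeLogEntry]]:
    """Rewrite every object's class term to its canonical class where a match
    exists; unmatched terms are left untouched and logged with matched_via
    "none".  Idempotent: already-canonical documents come back unchanged with
    an empty change log."""
    out = doc.copy()
    log: list[ChangeLogEntry] = []
    for obj in out.objects:
        res = normalize_term(schema, crosswalk, obj.class_term)
        if res.matched_via == "none":
            log.append(ChangeLogEntry(obj.id, obj.class_term, obj.class_term, "none"))
        elif obj.class_term != res.canonical_class:
            log.append(
                ChangeLogEntry(obj.id, obj.class_term, res.canonical_class, res.matched_via)
            )
            obj.class_term = res.canonical_class
    return out, log
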