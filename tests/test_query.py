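"""Separator-tolerant tokenization, the clause grammar, and evaluation."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from bma import (
    AnnotationDocument,
    AnnotationObject,
    QueryExpr,
    evaluate,
    parse_query,
    tokenize_list,
)
from bma.fixtures import generate_documents
from bma.query import QuerySyntaxError, UnknownQueryTermError
from bma.vocabulary import normalize_term


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("soma, axon | dendrite  synapse", ["soma", "axon", "dendrite", "synapse"]),
            ("soma", ["soma"]),
            (",,|  ,", []),
            ("A|B,C D", ["a", "b", "c", "d"]),
            ("", []),
        ],
    )
    def test_separator_runs(self, text, expected):
        assert tokenize_list(text) == expected

    @given(st.lists(st.sampled_from(["soma", "axon", "synapse", "bouton"]), max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_any_separator_mix_preserves_tokens(self, tokens):
        rng = random.Random(0)
        seps = [", ", " | ", " ", ",", "|", " , ", "  "]
        text = ""
        for t in tokens:
            text += t + rng.choice(seps)
        assert tokenize_list(text) == tokens


class TestParse:
    def test_conjunction_of_class_and_presence(self):
        q = parse_query("class=synapse & has=spine_id")
        assert [p.kind for p in q.predicates] == ["class_is", "has_property"]
        assert q.predicates[0].class_or_property == "synapse"
        assert q.predicates[1].class_or_property == "spine_id"

    def test_empty_query_matches_all(self):
        assert parse_query("") == QueryExpr()
        assert parse_query("   ") == QueryExpr()

    @pytest.mark.parametrize("bad", ["class=", "=x", "class=a b", "a & & b", "has=",
                                     "x in ,|", "justaword"])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(QuerySyntaxError):
            parse_query(bad)

    def test_property_in_lists_tolerate_any_separator(self):
        a = parse_query("confidence in high,medium")
        b = parse_query("confidence in high | medium")
        c = parse_query("confidence in high medium")
        assert a == b == c
        assert a.predicates[0].values == ("high", "medium")

    def test_property_equals(self):
        q = parse_query("region_name=cortex")
        assert q.predicates[0].kind == "property_equals"
        assert q.predicates[0].values == ("cortex",)


class TestEvaluate:
    def _collection(self):
        return [
            AnnotationDocument(
                schema_version="1.1.0",
                objects=[
                    AnnotationObject("s1", "synapse", {"spine_id": "sp-9"}),
                    AnnotationObject("s2", "synapse", {}),
                    AnnotationObject("c1", "soma", {}),
                ],
            )
        ]

    def test_class_and_presence_conjunction(self, schema, crosswalk):
        ids = evaluate(parse_query("class=synapse & has=spine_id"),
                       self._collection(), schema, crosswalk)
        assert ids == {"s1"}

    def test_empty_query_returns_all_ids(self, schema, crosswalk):
        ids = evaluate(QueryExpr(), self._collection(), schema, crosswalk)
        assert ids == {"s1", "s2", "c1"}

    def test_synonym_annotated_object_matches_canonical_class(self, schema, crosswalk):
        docs = [AnnotationDocument(
            schema_version="1.1.0",
            objects=[AnnotationObject("x", "Cell body", {})],
        )]
        assert evaluate(parse_query("class=soma"), docs, schema, crosswalk) == {"x"}

    def test_enum_matches_by_name_or_code(self, schema, crosswalk):
        docs = [AnnotationDocument(
            schema_version="1.1.0",
            objects=[
                AnnotationObject("h", "synapse", {"confidence": "high"}),
                AnnotationObject("l", "synapse", {"confidence": 0}),
            ],
        )]
        assert evaluate(parse_query("confidence=high"), docs, schema, crosswalk) == {"h"}
        assert evaluate(parse_query("confidence=2"), docs, schema, crosswalk) == {"h"}
        assert evaluate(parse_query("confidence=low"), docs, schema, crosswalk) == {"l"}

    def test_unknown_property_raises_with_suggestions(self, schema, crosswalk):
        with pytest.raises(UnknownQueryTermError) as exc:
            evaluate(parse_query("has=spine_idd"), self._collection(), schema, crosswalk)
        assert any(t == "spine_id" for t, _ in exc.value.suggestions)

    def test_adding_a_predicate_never_enlarges_results(self, schema, crosswalk):
        docs = generate_documents(schema, 150, seed=13)
        base = evaluate(parse_query("class=synapse"), docs, schema, crosswalk)
        narrowed = evaluate(parse_query("class=synapse & has=spine_id"), docs, schema, crosswalk)
        assert narrowed <= base


def _oracle_value_eq(raw, wanted, schema, pname):
    """Value comparison re-implemented from the documented semantics."""
    from bma.schema_core import PropertyType

    if isinstance(raw, bool):
        return wanted in (("true", "1") if raw else ("false", "0"))
    spec = schema.property_spec(pname)
    if spec is not None and spec.ptype is PropertyType.ENUMERATION:
        enum = schema.enum_by_name(spec.enum_ref)
        for v in enum.values:
            hit = (isinstance(raw, str) and raw.lower() == v.name.lower()) or raw == v.code
            if hit:
                return wanted.lower() in (v.name.lower(), str(v.code))
        return str(raw).lower() == wanted.lower()
    if isinstance(raw, (int, float)):
        try:
            return float(raw) == float(wanted)
        except ValueError:
            return False
    return str(raw).lower() == wanted.lower()


def naive_scan(q, docs, schema, crosswalk):
    """Independent object-by-object full-scan oracle."""
    out = set()
    for doc in docs:
        for obj in doc.objects:
            canonical = normalize_term(schema, crosswalk, obj.class_term).canonical_class
            ok = True
            for p in q.predicates:
                if p.kind == "class_is":
                    want = normalize_term(schema, crosswalk, p.class_or_property)
                    ok = canonical == (want.canonical_class or p.class_or_property)
                elif p.kind == "has_property":
                    ok = p.class_or_property in obj.properties
                elif p.kind == "property_equals":
                    ok = p.class_or_property in obj.properties and _oracle_value_eq(
                        obj.properties[p.class_or_property], p.values[0], schema,
                        p.class_or_property)
                else:  # property_in
                    ok = p.class_or_property in obj.properties and any(
                        _oracle_value_eq(obj.properties[p.class_or_property], w,
                                         schema, p.class_or_property)
                        for w in p.values
                    )
                if not ok:
                    break
            if ok:
                out.add(obj.id)
    return out


def random_query(rng, schema):
    clauses = []
    for _ in range(rng.randint(1, 3)):
        kind = rng.choice(["class", "has", "eq", "in"])
        if kind == "class":
            clauses.append(f"class={rng.choice([c.name for c in schema.classes])}")
        elif kind == "has":
            prop = rng.choice([p.name for _, p in schema.iter_properties()])
            clauses.append(f"has={prop}")
        elif kind == "eq":
            clauses.append(rng.choice([
                "confidence=high", "apical=true", "myelinated=false",
                "region_name=cortex", "interneurons=putative_interneuron",
            ]))
        else:
            clauses.append(rng.choice([
                "confidence in high,medium", "interneurons in interneuron | unknown",
                "region_name in cortex,thalamus",
            ]))
    return " & ".join(clauses)


class TestOracleEquivalence:
    def test_matches_naive_scan_on_seeded_collection(self, schema, crosswalk):
        docs = generate_documents(schema, 300, seed=21)
        rng = random.Random(99)
        for _ in range(25):
            text = random_query(rng, schema)
            q = parse_query(text)
            resolved_ids = evaluate(q, docs, schema, crosswalk)
            # the oracle sees the resolved query (class tokens canonicalized)
            assert resolved_ids == naive_scan(q, docs, schema, crosswalk), text

    def test_separator_rewrites_never_change_results(self, schema, crosswalk):
        docs = generate_documents(schema, 200, seed=22)
        variants = [
            "confidence in high,medium",
            "confidence in high | medium",
            "confidence in high  medium",
            "confidence in high,|medium",
        ]
        results = {frozenset(evaluate(parse_query(v), docs, schema, crosswalk))
                   for v in variants}
        assert len(results) == 1
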