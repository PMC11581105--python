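"""Crosswalk loading, term normalization and edit-distance suggestions."""

import pytest

from bma import (
    AnnotationDocument,
    AnnotationObject,
    CrosswalkError,
    load_crosswalk,
    normalize_document,
    normalize_term,
    suggest_terms,
)
from bma.fixtures import generate_documents, table1_fixture
from bma.vocabulary import known_terms, levenshtein


def dp_levenshtein(a: str, b: str) -> int:
    """Independent brute-force dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestCrosswalkLoading:
    def test_every_study_column_is_loaded(self, crosswalk):
        assert len(crosswalk.studies) == 7

    def test_passant_boutons_maps_to_bouton(self, crosswalk):
        hits = [e for e in crosswalk.entries if e.source_term == "Passant boutons"]
        assert len(hits) == 1
        assert hits[0].canonical_class == "bouton"
        assert hits[0].source_study == "Witvliet et al. 2020"

    def test_multi_term_cell_splits_into_one_entry_per_term(self, crosswalk):
        kasthuri = [e.source_term for e in crosswalk.entries
                    if e.source_study == "Kasthuri et al. 2015" and e.canonical_class == "neuron"]
        assert sorted(kasthuri) == ["Neuron", "Neuronal somata"]

    def test_prasad_region_cell_splits_on_commas_and_and(self, crosswalk):
        prasad = {e.source_term for e in crosswalk.entries
                  if e.source_study == "Prasad et al. 2020"
                  and e.canonical_class == "region_of_interest"}
        assert prasad == {"Cortex", "Striatum", "Thalamus", "Zona Incerta"}

    def test_na_cells_produce_no_entries(self, crosswalk):
        assert all(e.source_term.upper() != "NA" for e in crosswalk.entries)

    def test_conflicting_mapping_rejected(self, schema):
        text = "Annotations,Study A\nSynapse,Thing\nSoma,Thing\n"
        with pytest.raises(CrosswalkError, match="conflicting"):
            load_crosswalk(text, schema)

    def test_unknown_row_label_rejected(self, schema):
        text = "Annotations,Study A\nMitochondrion,Mito\n"
        with pytest.raises(CrosswalkError, match="no schema class"):
            load_crosswalk(text, schema)

    def test_tsv_accepted(self, schema):
        text = "Annotations\tStudy A\nSynapse\tSynapse\n"
        table = load_crosswalk(text, schema)
        assert table.lookup("synapse") == "synapse"


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "term,expected_class,via",
        [
            ("soma", "soma", "exact"),
            ("Synapse", "synapse", "exact"),
            ("Cell Body", "soma", "synonym"),
            ("cell body", "soma", "synonym"),
            ("Passant boutons", "bouton", "crosswalk"),
            ("Putative interneurons", "interneuron", "crosswalk"),
            ("Molecular layer interneurons", "interneuron", "crosswalk"),
            ("Clefts", "synaptic_cleft", "crosswalk"),
            ("Interneurons", "interneuron", "exact"),  # plural folds to the class
            ("Zona Incerta", "region_of_interest", "crosswalk"),
        ],
    )
    def test_matching_order_and_folding(self, schema, crosswalk, term, expected_class, via):
        res = normalize_term(schema, crosswalk, term)
        assert (res.canonical_class, res.matched_via) == (expected_class, via)

    def test_unmatched_term_gets_suggestions_only(self, schema, crosswalk):
        res = normalize_term(schema, crosswalk, "snyapse")
        assert res.canonical_class == ""
        assert res.matched_via == "none"
        assert res.suggestions[0][0].lower() == "synapse"

    def test_matched_terms_carry_no_suggestions(self, schema, crosswalk):
        assert normalize_term(schema, crosswalk, "soma").suggestions == ()


class TestSuggestTerms:
    def test_unique_term_at_distance_two(self, schema, crosswalk):
        vocab = known_terms(schema, crosswalk)
        assert suggest_terms(vocab, "snyapse", 2) == [("synapse", 2)]

    def test_exact_matches_excluded(self, schema, crosswalk):
        assert suggest_terms(known_terms(schema, crosswalk), "synapse", 0) == []

    def test_nothing_within_distance_one_of_garbage(self, schema, crosswalk):
        assert suggest_terms(known_terms(schema, crosswalk), "zzzzzz", 1) == []

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            suggest_terms(["soma"], "x", -1)

    @pytest.mark.parametrize("probe", ["snyapse", "somaa", "boutn", "celll body",
                                       "gap junctin", "spine aparatus", "nueron"])
    @pytest.mark.parametrize("max_distance", [0, 1, 2, 3])
    def test_agrees_with_brute_force_oracle(self, schema, crosswalk, probe, max_distance):
        from bma.schema_core import term_key

        vocab = known_terms(schema, crosswalk)
        got = suggest_terms(vocab, probe, max_distance)
        keys = {}
        for v in vocab:
            k = term_key(v)
            if k != term_key(probe):
                keys.setdefault(k, dp_levenshtein(term_key(probe), k))
        expected = sorted(
            ((k, d) for k, d in keys.items() if d <= max_distance),
            key=lambda t: (t[1], t[0]),
        )
        assert [(term_key(t), d) for t, d in got] == expected

    def test_engine_matches_dp_distance_pairwise(self, schema, crosswalk):
        vocab = [t.lower() for t in known_terms(schema, crosswalk)]
        for a in vocab[:10]:
            for b in vocab[:10]:
                assert levenshtein(a, b) == dp_levenshtein(a, b)


class TestNormalizeDocument:
    def _doc(self, *terms):
        return AnnotationDocument(
            schema_version="1.1.0",
            objects=[
                AnnotationObject(id=f"o{i}", class_term=t) for i, t in enumerate(terms)
            ],
        )

    def test_legacy_terms_rewritten_and_logged(self, schema, crosswalk):
        doc = self._doc("Cell body", "Passant boutons", "synapse")
        out, log = normalize_document(schema, crosswalk, doc)
        assert [o.class_term for o in out.objects] == ["soma", "bouton", "synapse"]
        assert [(e.path, e.old_term, e.new_term) for e in log] == [
            ("o0", "Cell body", "soma"),
            ("o1", "Passant boutons", "bouton"),
        ]

    def test_canonical_document_is_untouched(self, schema, crosswalk):
        doc = self._doc("soma", "synapse")
        out, log = normalize_document(schema, crosswalk, doc)
        assert out.to_json() == doc.to_json()
        assert log == []

    def test_idempotent(self, schema, crosswalk):
        doc = self._doc("Cell body", "Clefts", "Putative synapses")
        once, _ = normalize_document(schema, crosswalk, doc)
        twice, log2 = normalize_document(schema, crosswalk, once)
        assert twice.to_json() == once.to_json()
        assert log2 == []

    def test_unmatched_terms_left_untouched_and_logged(self, schema, crosswalk):
        doc = self._doc("mystery blob")
        out, log = normalize_document(schema, crosswalk, doc)
        assert out.objects[0].class_term == "mystery blob"
        assert log[0].matched_via == "none"

    def test_clean_fixture_docs_need_no_normalization(self, schema, crosswalk, clean_docs):
        for doc in clean_docs[:3]:
            out, log = normalize_document(schema, crosswalk, doc)
            assert log == []


class TestTable1Totality:
    def test_every_non_na_cell_normalizes_to_its_rows_class(self, schema, crosswalk):
        import csv
        import io

        rows = list(csv.reader(io.StringIO(table1_fixture())))
        header, data = rows[0], rows[1:]
        checked = 0
        for row in data:
            row_class, _ = schema.resolve_class_term(row[0])
            assert row_class
            for cell in row[1:]:
                cell = cell.strip()
                if not cell or cell.upper() == "NA":
                    continue
                from bma.vocabulary import _split_cell

                for term in _split_cell(cell):
                    res = normalize_term(schema, crosswalk, term)
                    assert res.matched_via != "none", term
                    assert res.canonical_class == row_class, (term, row_class)
                    checked += 1
        assert checked >= 40
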