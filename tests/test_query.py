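"""Query parsing and Boolean evaluation against per-document predicates."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from markermine.annotate import Document, annotate_corpus, compile_matcher
from markermine.corpus_index import build_index
from markermine.query import (
    DocSet,
    QueryAST,
    QuerySyntaxError,
    UnknownTermError,
    entity_table,
    evaluate_query,
    parse_query,
)

from conftest import build_terminology


def _disease_term():
    return build_terminology(
        [("Disease", "Diseases", None), ("Evidence", "Evidence marker", None),
         ("Genes", "Human Genes/Proteins", None)],
        [
            ("AD", "Disease", ["Alzheimer's Disease", "alzheimer disease"]),
            ("EV:expr", "Evidence", ["expression"]),
            ("EV:mut", "Evidence", ["mutation"]),
            ("APP", "Genes", [("APP", True), "amyloid precursor protein"]),
            ("APOE", "Genes", [("APOE", True)]),
        ],
    )


def _corpus(term, texts):
    docs = [Document(doc_id=d, title="", abstract=t) for d, t in texts.items()]
    anns = annotate_corpus(compile_matcher(term), docs)
    return docs, build_index(docs, anns)


def _five_doc_index(term):
    texts = {
        "d1": "Alzheimer's Disease progression in a cohort",
        "d2": "Alzheimer disease and APP expression changes",
        "d3": "expression and mutation of APOE",
        "d4": "unrelated text about tumors",
        "d5": "APP binds APOE with no disease context",
    }
    return _corpus(term, texts)


@pytest.fixture
def disease_term():
    return _disease_term()


@pytest.fixture
def five_doc_index(disease_term):
    return _five_doc_index(disease_term)


# shared, read-only instances for the hypothesis property tests (no pytest
# fixture: hypothesis requires stable inputs across generated examples)
_TERM = _disease_term()
_DOCS, _INDEX = _five_doc_index(_TERM)


class TestParse:
    def test_disease_and_class_query(self, disease_term):
        ast = parse_query('"Alzheimer\'s Disease" AND [Evidence]', disease_term)
        assert ast.kind == "AND"
        assert ast.children[0] == QueryAST("CONCEPT", value="AD")
        assert ast.children[1] == QueryAST("CLASS", value="Evidence")

    def test_quoted_class_name_falls_back_to_class(self, disease_term):
        ast = parse_query("'Evidence marker'", disease_term)
        assert ast == QueryAST("CLASS", value="Evidence")

    def test_precedence_and_binds_tighter_than_or(self, disease_term):
        ast = parse_query("a AND b OR c", disease_term)
        assert ast.kind == "OR"
        assert ast.children[0].kind == "AND"
        assert ast.children[1] == QueryAST("TEXT", value="c")

    def test_not_binds_tightest(self, disease_term):
        ast = parse_query("NOT a AND b", disease_term)
        assert ast.kind == "AND"
        assert ast.children[0].kind == "NOT"

    def test_unbalanced_paren_reports_position(self, disease_term):
        with pytest.raises(QuerySyntaxError) as exc:
            parse_query("(a OR b", disease_term)
        assert exc.value.position == 0

    def test_unbalanced_quote_raises(self, disease_term):
        with pytest.raises(QuerySyntaxError):
            parse_query('"unclosed', disease_term)

    def test_unknown_quoted_name_lists_near_matches(self, disease_term):
        with pytest.raises(UnknownTermError) as exc:
            parse_query('"Alzheimers Diseas"', disease_term)
        assert exc.value.suggestions  # at least one near-match offered

    def test_resolution_case_insensitive(self, disease_term):
        assert parse_query('"ALZHEIMER DISEASE"', disease_term).value == "AD"
        assert parse_query("[evidence]", disease_term).value == "Evidence"


class TestEvaluate:
    def test_class_node_unions_subtree_entries(self, five_doc_index, disease_term):
        _, index = five_doc_index
        got = evaluate_query(index, parse_query("[Evidence]", disease_term), disease_term)
        assert got.doc_ids == {"d2", "d3"}

    def test_contradiction_is_empty(self, five_doc_index, disease_term):
        _, index = five_doc_index
        got = evaluate_query(
            index, parse_query('"expression" AND NOT "expression"', disease_term), disease_term
        )
        assert got.doc_ids == set()

    def test_not_is_closed_world_complement(self, five_doc_index, disease_term):
        _, index = five_doc_index
        x = evaluate_query(index, parse_query("NOT (mutation OR expression)", disease_term),
                           disease_term)
        # truth-table oracle: docs whose text contains neither token
        expected = set()
        for d in index.documents.values():
            text = (d.title + " " + d.abstract).lower()
            if "mutation" not in text and "expression" not in text:
                expected.add(d.doc_id)
        assert x.doc_ids == expected

    def test_disease_and_class_intersection(self, five_doc_index, disease_term):
        _, index = five_doc_index
        got = evaluate_query(
            index,
            parse_query('"Alzheimer\'s Disease" AND [Evidence]', disease_term),
            disease_term,
        )
        assert got.doc_ids == {"d2"}  # {d1,d2} disease ∩ {d2,d3} evidence

    def test_text_token_is_bounded_and_wildcard_prefixes(self, disease_term):
        _, index = _corpus(disease_term, {
            "d1": "tumor growth", "d2": "tumors everywhere", "d3": "the tumorigenesis process",
        })
        exact = evaluate_query(index, parse_query("tumor", disease_term), disease_term)
        assert exact.doc_ids == {"d1"}
        pref = evaluate_query(index, parse_query("tumor*", disease_term), disease_term)
        assert pref.doc_ids == {"d1", "d2", "d3"}


class TestEntityTable:
    def test_empty_docset(self, five_doc_index, disease_term):
        _, index = five_doc_index
        assert entity_table(index, DocSet(set()), "Genes", disease_term) == []

    def test_all_docs_equals_global_frequency(self, five_doc_index, disease_term):
        _, index = five_doc_index
        table = dict(entity_table(index, DocSet(index.doc_ids()), "Genes", disease_term))
        assert table == {"APP": 2, "APOE": 2}

    def test_counts_restricted_to_docset(self, five_doc_index, disease_term):
        _, index = five_doc_index
        table = dict(entity_table(index, DocSet({"d1", "d2", "d3"}), "Genes", disease_term))
        assert table == {"APP": 1, "APOE": 1}


# ---------------------------------------------------------------------------
# Property: evaluate_query agrees with exhaustive per-document predicates
# ---------------------------------------------------------------------------


def _predicate(node, doc, term, index):
    """Brute-force truth of an AST for one document."""
    if node.kind == "CONCEPT":
        return doc.doc_id in index.entry_postings(node.value)
    if node.kind == "CLASS":
        from markermine.terminology import entries_in, subtree
        for entry in entries_in(term, subtree(term, node.value)):
            if doc.doc_id in index.entry_postings(entry.entry_id):
                return True
        return False
    if node.kind == "TEXT":
        prefix = node.value.endswith("*")
        body = re.escape(node.value[:-1] if prefix else node.value)
        pat = r"(?<![^\W_])" + body + ("" if prefix else r"(?![^\W_])")
        rx = re.compile(pat, re.IGNORECASE)
        return bool(rx.search(doc.title) or rx.search(doc.abstract))
    if node.kind == "AND":
        return _predicate(node.children[0], doc, term, index) and \
            _predicate(node.children[1], doc, term, index)
    if node.kind == "OR":
        return _predicate(node.children[0], doc, term, index) or \
            _predicate(node.children[1], doc, term, index)
    if node.kind == "NOT":
        return not _predicate(node.children[0], doc, term, index)
    raise AssertionError(node.kind)


def _ast_strategy():
    leaves = st.one_of(
        st.sampled_from([QueryAST("CONCEPT", value=v) for v in ("AD", "EV:expr", "APP", "APOE")]),
        st.sampled_from([QueryAST("CLASS", value=v) for v in ("Disease", "Evidence", "Genes")]),
        st.sampled_from([QueryAST("TEXT", value=v) for v in ("tumor", "cohort", "tumor*", "disease")]),
    )
    return st.recursive(
        leaves,
        lambda inner: st.one_of(
            st.tuples(inner, inner).map(lambda c: QueryAST("AND", children=c)),
            st.tuples(inner, inner).map(lambda c: QueryAST("OR", children=c)),
            inner.map(lambda c: QueryAST("NOT", children=(c,))),
        ),
        max_leaves=6,
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(ast=_ast_strategy())
def test_evaluate_matches_per_document_predicate(ast):
    docs, index, disease_term = _DOCS, _INDEX, _TERM
    got = evaluate_query(index, ast, disease_term).doc_ids
    expected = {d.doc_id for d in docs if _predicate(ast, d, disease_term, index)}
    assert got == expected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=_ast_strategy(), b=_ast_strategy())
def test_de_morgan_laws(a, b):
    index, disease_term = _INDEX, _TERM
    lhs = evaluate_query(
        index, QueryAST("NOT", children=(QueryAST("OR", children=(a, b)),)), disease_term
    ).doc_ids
    rhs = evaluate_query(
        index,
        QueryAST("AND", children=(QueryAST("NOT", children=(a,)), QueryAST("NOT", children=(b,)))),
        disease_term,
    ).doc_ids
    assert lhs == rhs


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=_ast_strategy(), b=_ast_strategy())
def test_and_clause_never_enlarges_docset(a, b):
    index, disease_term = _INDEX, _TERM
    base = evaluate_query(index, a, disease_term).doc_ids
    anded = evaluate_query(index, QueryAST("AND", children=(a, b)), disease_term).doc_ids
    assert anded <= base


def test_entity_table_counts_shrink_with_docset(disease_term, five_doc_index):
    _, index = five_doc_index
    big = dict(entity_table(index, DocSet(index.doc_ids()), "Genes", disease_term))
    small = dict(entity_table(index, DocSet({"d2", "d5"}), "Genes", disease_term))
    for entry, count in small.items():
        assert count <= big[entry]
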