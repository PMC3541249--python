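"""Boolean semantic queries over an annotated corpus index.

A query combines three kinds of leaves — dictionary concepts (quoted names
that resolve to a terminology entry), terminology classes (quoted names
falling back to a class, or ``[Bracketed]`` names forcing a class), and bare
free-text tokens — with ``NOT`` > ``AND`` > ``OR`` precedence and
parentheses.  A class leaf stands for the union of every entry anywhere in
the class's subtree, so selecting e.g. ``[Evidence]`` retrieves all
abstracts containing one or more terms of that branch of the terminology.
``NOT`` is a closed-world complement against the evaluated index's document
set.  A trailing ``*`` on a bare token requests a prefix match.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .corpus_index import CorpusIndex
from .terminology import Terminology, entries_in, subtree

__all__ = [
    "QueryAST",
    "DocSet",
    "QuerySyntaxError",
    "UnknownTermError",
    "parse_query",
    "evaluate_query",
    "entity_table",
]

logger = logging.getLogger(__name__)


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class UnknownTermError(ValueError):
    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean {suggestions}?" if suggestions else ""
        super().__init__(f"unresolvable quoted name {name!r}{hint}")


@dataclass(frozen=True)
class QueryAST:
    """One node of a parsed query.

    kind is CONCEPT / CLASS / TEXT (leaves, with ``value`` set) or
    AND / OR (two children) / NOT (one child).
    """

    kind: str
    value: Optional[str] = None
    children: tuple["QueryAST", ...] = field(default_factory=tuple)

    def __post_init__(self):
        arity = {"AND": 2, "OR": 2, "NOT": 1, "CONCEPT": 0, "CLASS": 0, "TEXT": 0}
        if self.kind not in arity:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if len(self.children) != arity[self.kind]:
            raise ValueError(f"{self.kind} takes {arity[self.kind]} children")


@dataclass
class DocSet:
    doc_ids: set[str]
    query_text: str = ""

    def __len__(self) -> int:
        return len(self.doc_ids)


# ---------------------------------------------------------------------------
# Lexer / parser (recursive descent, NOT > AND > OR)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"""\s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<quoted>"(?P<q2>[^"]*)"|'(?P<q1>[^']*)') |
        (?P<bracket>\[(?P<b>[^\]]*)\]) |
        (?P<word>[^\s()\[\]"']+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            remainder = text[pos:].strip()
            if not remainder:
                break
            if remainder[0] in "\"'":
                raise QuerySyntaxError("unbalanced quote", pos + text[pos:].index(remainder[0]))
            if remainder[0] == "[":
                raise QuerySyntaxError("unbalanced bracket", pos)
            raise QuerySyntaxError(f"cannot tokenize {remainder[:10]!r}", pos)
        if m.end() == m.start():
            break
        start = m.start() + (len(m.group(0)) - len(m.group(0).lstrip()))
        if m.group("lparen"):
            tokens.append(("LPAREN", "(", start))
        elif m.group("rparen"):
            tokens.append(("RPAREN", ")", start))
        elif m.group("quoted") is not None:
            body = m.group("q2") if m.group("q2") is not None else m.group("q1")
            tokens.append(("QUOTED", body, start))
        elif m.group("bracket") is not None:
            tokens.append(("BRACKET", m.group("b"), start))
        else:
            word = m.group("word")
            if word.upper() in ("AND", "OR", "NOT"):
                tokens.append((word.upper(), word, start))
            else:
                tokens.append(("WORD", word, start))
        pos = m.end()
    return tokens


def _resolve_quoted(name: str, term: Terminology) -> QueryAST:
    """Quoted names resolve to a CONCEPT when they name an entry (preferred
    name or synonym), falling back to a CLASS when they name a class."""
    key = name.strip().casefold()
    concept: Optional[str] = None
    for entry in term.entries.values():
        if entry.preferred_name.casefold() == key or any(
            s.text.casefold() == key for s in entry.synonyms
        ):
            concept = entry.entry_id if concept is None else min(concept, entry.entry_id)
    klass = _resolve_class(name, term)
    if concept is not None:
        if klass is not None:
            logger.warning(
                "quoted name %r names both entry %r and class %r; using the entry",
                name, concept, klass,
            )
        return QueryAST("CONCEPT", value=concept)
    if klass is not None:
        return QueryAST("CLASS", value=klass)
    universe = sorted(
        {e.preferred_name for e in term.entries.values()}
        | {c.name for c in term.classes.values()}
        | set(term.classes)
    )
    raise UnknownTermError(name, difflib.get_close_matches(name, universe, n=3))


def _resolve_class(name: str, term: Terminology) -> Optional[str]:
    key = name.strip().casefold()
    hits = sorted(
        c.class_id
        for c in term.classes.values()
        if c.class_id.casefold() == key or c.name.casefold() == key
    )
    return hits[0] if hits else None


def parse_query(text: str, term: Terminology) -> QueryAST:
    """Parse a Boolean query string against a terminology.

    Grammar: ``or := and (OR and)*``, ``and := not (AND not)*``,
    ``not := NOT not | atom``, ``atom := ( or ) | quoted | [class] | word``.
    Name resolution is case-insensitive.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> Optional[tuple[str, str, int]]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[str, str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> QueryAST:
        node = parse_and()
        while peek() is not None and peek()[0] == "OR":
            take()
            node = QueryAST("OR", children=(node, parse_and()))
        return node

    def parse_and() -> QueryAST:
        node = parse_not()
        while peek() is not None and peek()[0] == "AND":
            take()
            node = QueryAST("AND", children=(node, parse_not()))
        return node

    def parse_not() -> QueryAST:
        if peek() is not None and peek()[0] == "NOT":
            take()
            return QueryAST("NOT", children=(parse_not(),))
        return parse_atom()

    def parse_atom() -> QueryAST:
        tok = peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", len(text))
        kind, value, at = take()
        if kind == "LPAREN":
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != "RPAREN":
                raise QuerySyntaxError("unbalanced parenthesis", at)
            take()
            return node
        if kind == "QUOTED":
            return _resolve_quoted(value, term)
        if kind == "BRACKET":
            cid = _resolve_class(value, term)
            if cid is None:
                universe = sorted(set(term.classes) | {c.name for c in term.classes.values()})
                raise UnknownTermError(value, difflib.get_close_matches(value, universe, n=3))
            return QueryAST("CLASS", value=cid)
        if kind == "WORD":
            return QueryAST("TEXT", value=value)
        raise QuerySyntaxError(f"unexpected token {value!r}", at)

    if not tokens:
        raise QuerySyntaxError("empty query", 0)
    node = parse_or()
    if peek() is not None:
        raise QuerySyntaxError(f"trailing input {peek()[1]!r}", peek()[2])
    return node


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _text_postings(index: CorpusIndex, token: str) -> set[str]:
    """Documents whose title or abstract contains the token (case-insensitive,
    token-bounded); a trailing ``*`` requests a prefix match."""
    prefix = token.endswith("*")
    body = re.escape(token[:-1] if prefix else token)
    if not body:
        return set()
    pat = r"(?<![^\W_])" + body + ("" if prefix else r"(?![^\W_])")
    rx = re.compile(pat, re.IGNORECASE)
    return {
        d.doc_id
        for d in index.documents.values()
        if rx.search(d.title) or rx.search(d.abstract)
    }


def evaluate_query(index: CorpusIndex, ast: QueryAST, term: Terminology) -> DocSet:
    """Evaluate an AST to the set of matching documents in *index*."""

    def ev(node: QueryAST) -> set[str]:
        if node.kind == "CONCEPT":
            return index.entry_postings(node.value)
        if node.kind == "CLASS":
            class_ids = subtree(term, node.value)
            out: set[str] = set()
            for entry in entries_in(term, class_ids):
                out |= index.entry_postings(entry.entry_id)
            return out
        if node.kind == "TEXT":
            return _text_postings(index, node.value)
        if node.kind == "AND":
            return ev(node.children[0]) & ev(node.children[1])
        if node.kind == "OR":
            return ev(node.children[0]) | ev(node.children[1])
        if node.kind == "NOT":
            return index.doc_ids() - ev(node.children[0])
        raise ValueError(f"unknown node kind {node.kind!r}")

    return DocSet(doc_ids=ev(ast))


def entity_table(
    index: CorpusIndex, docset: DocSet, class_id: str, term: Terminology
) -> list[tuple[str, int]]:
    """Per-entry document counts within *docset* for a class subtree.

    Zero-count entries are omitted; output is sorted by entry_id for
    determinism (ranking applies its own order downstream).
    """
    class_ids = subtree(term, class_id)
    selected = docset.doc_ids
    table: list[tuple[str, int]] = []
    for entry in entries_in(term, class_ids):
        count = len(index.entry_postings(entry.entry_id) & selected)
        if count > 0:
            table.append((entry.entry_id, count))
    table.sort(key=lambda t: t[0])
    return table
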