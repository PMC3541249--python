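"""Deterministic dictionary matching of terminology synonyms in abstracts.

The matcher compiles every synonym of a terminology into one alternation
pattern and scans title and abstract separately, producing character-offset
annotations normalized to terminology entries.  Matching rules:

* token boundaries — a match must be flanked by non-alphanumeric characters
  or the string edges (so "MS" never fires inside "MSH2");
* case policy — case-sensitive synonyms match exactly, case-insensitive
  synonyms match under Unicode case folding;
* separator folding — runs of whitespace and hyphens on either side count
  as a single separator, so the synonym "Kaplan Meier" matches the surface
  form "Kaplan-Meier";
* overlaps — resolved leftmost-longest in a single greedy pass; among
  candidates covering the identical span the lexicographically smallest
  entry_id wins.

The matcher's behaviour is extensionally identical to the naive oracle that
scans the text once per synonym (the property suite asserts this).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

from .terminology import Terminology

__all__ = [
    "Document",
    "Annotation",
    "Matcher",
    "compile_matcher",
    "annotate_document",
    "annotate_corpus",
    "resolve_overlaps",
]

logger = logging.getLogger(__name__)

#: Fields of a document that are annotated, in reading order.
FIELDS = ("title", "abstract")
_FIELD_ORDER = {f: i for i, f in enumerate(FIELDS)}

# A boundary character is anything that is not alphanumeric; [^\W_] is the
# Unicode-aware alphanumeric class (word chars minus underscore).
_BOUND_L = r"(?<![^\W_])"
_BOUND_R = r"(?![^\W_])"
_SEP = re.compile(r"[\s\-]+")


@dataclass(frozen=True)
class Document:
    """An abstract-level record with a PMID-like identifier."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    date: Optional[str] = None


@dataclass(frozen=True)
class Annotation:
    """One entity mention: a half-open character span in one document field."""

    doc_id: str
    field: str
    start: int
    end: int
    matched_text: str
    entry_id: str
    class_id: str


def _collapse(text: str) -> str:
    """Fold hyphen/whitespace runs to single spaces (the separator contract)."""
    return _SEP.sub(" ", text).strip()


def _synonym_pattern(text: str, case_sensitive: bool) -> str:
    parts = [re.escape(p) for p in _collapse(text).split(" ")]
    body = r"[\s\-]+".join(parts)
    return body if case_sensitive else f"(?i:{body})"


class Matcher:
    """Compiled multi-synonym scanner; build with :func:`compile_matcher`."""

    def __init__(self, term: Terminology):
        self._ci: dict[str, list[tuple[str, str]]] = {}  # collapsed casefold -> [(entry, class)]
        self._cs: dict[str, list[tuple[str, str]]] = {}  # collapsed exact    -> [(entry, class)]
        alts: list[tuple[int, str]] = []
        seen: set[tuple[str, bool]] = set()
        for entry in term.entries.values():
            for syn in entry.synonyms:
                collapsed = _collapse(syn.text)
                if not collapsed:
                    continue
                pair = (entry.entry_id, entry.class_id)
                if syn.case_sensitive:
                    self._cs.setdefault(collapsed, [])
                    if pair not in self._cs[collapsed]:
                        self._cs[collapsed].append(pair)
                else:
                    key = collapsed.casefold()
                    self._ci.setdefault(key, [])
                    if pair not in self._ci[key]:
                        self._ci[key].append(pair)
                sig = (collapsed if syn.case_sensitive else collapsed.casefold(), syn.case_sensitive)
                if sig not in seen:
                    seen.add(sig)
                    alts.append((len(collapsed), _synonym_pattern(collapsed, syn.case_sensitive)))
        if not alts:
            logger.warning("compiling matcher over empty terminology: matches nothing")
            self._regex: Optional[re.Pattern] = None
            return
        # Longer (normalized) alternatives first so the leftmost match is also
        # the longest one available at its start position.
        alts.sort(key=lambda t: (-t[0], t[1]))
        pattern = _BOUND_L + "(?:" + "|".join(p for _, p in alts) + ")" + _BOUND_R
        self._regex = re.compile(pattern)

    def candidates(self, text: str) -> list[tuple[int, int, str, list[tuple[str, str]]]]:
        """Non-overlapping leftmost-longest spans with all entries per span."""
        if self._regex is None:
            return []
        out = []
        for m in self._regex.finditer(text):
            surface = m.group(0)
            collapsed = _collapse(surface)
            pairs = list(self._ci.get(collapsed.casefold(), ()))
            for pair in self._cs.get(collapsed, ()):
                if pair not in pairs:
                    pairs.append(pair)
            if pairs:
                out.append((m.start(), m.end(), surface, pairs))
        return out


def compile_matcher(term: Terminology) -> Matcher:
    """Compile a terminology into a reusable matcher."""
    term.validate()
    return Matcher(term)


def annotate_document(matcher: Matcher, doc: Document) -> list[Annotation]:
    """All maximal, token-bounded, policy-respecting matches, overlap-resolved.

    Title and abstract are scanned independently; offsets index into the
    named field.  Output is sorted by (field reading order, start).
    """
    out: list[Annotation] = []
    for field_name in FIELDS:
        text = getattr(doc, field_name)
        for start, end, surface, pairs in matcher.candidates(text):
            entry_id, class_id = min(pairs)  # equal span -> lexicographic entry tie-break
            out.append(
                Annotation(
                    doc_id=doc.doc_id,
                    field=field_name,
                    start=start,
                    end=end,
                    matched_text=surface,
                    entry_id=entry_id,
                    class_id=class_id,
                )
            )
    return out


def annotate_corpus(matcher: Matcher, docs: list[Document]) -> list[Annotation]:
    anns: list[Annotation] = []
    for doc in docs:
        anns.extend(annotate_document(matcher, doc))
    return anns


def resolve_overlaps(candidates: list[Annotation]) -> list[Annotation]:
    """Greedy leftmost-longest selection of a non-overlapping subset.

    All candidates must come from one document.  Among candidates with the
    identical span, the lexicographically smallest entry_id is kept.
    """
    if not candidates:
        return []
    doc_ids = {c.doc_id for c in candidates}
    if len(doc_ids) > 1:
        raise ValueError(f"candidates span multiple documents: {sorted(doc_ids)}")
    ordered = sorted(
        candidates,
        key=lambda a: (_FIELD_ORDER.get(a.field, 99), a.start, -(a.end - a.start), a.entry_id),
    )
    kept: list[Annotation] = []
    last_field: Optional[str] = None
    last_end = 0
    for cand in ordered:
        if cand.field != last_field:
            last_field = cand.field
            last_end = 0
        if cand.start >= last_end:
            kept.append(cand)
            last_end = cand.end
    return kept
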