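"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import pytest

from markermine.annotate import Annotation, Document
from markermine.terminology import (
    Terminology,
    TermClass,
    TermEntry,
    make_synonym,
)

# ---------------------------------------------------------------------------
# Independent naive matching oracle: scan the text once per synonym, find
# every occurrence (including overlapping ones) that respects the case
# policy and token boundaries, then resolve greedily leftmost-longest with
# the lexicographic entry tie-break.  Deliberately slow and simple.
# ---------------------------------------------------------------------------


def _collapse(text: str) -> str:
    return re.sub(r"[\s\-]+", " ", text).strip()


def naive_candidates(term: Terminology, text: str):
    """(start, end, entry_id, class_id) for every synonym occurrence."""
    out = []
    for entry in term.entries.values():
        for syn in entry.synonyms:
            parts = [re.escape(p) for p in _collapse(syn.text).split(" ") if p]
            if not parts:
                continue
            body = r"[\s\-]+".join(parts)
            flags = 0 if syn.case_sensitive else re.IGNORECASE
            # capturing lookahead finds occurrences at every start position
            rx = re.compile(r"(?<![^\W_])(?=(" + body + r")(?![^\W_]))", flags)
            for m in rx.finditer(text):
                out.append((m.start(1), m.end(1), entry.entry_id, entry.class_id))
    return out


def naive_annotate(term: Terminology, doc: Document) -> list[Annotation]:
    """Greedy leftmost-longest resolution of the naive candidate set."""
    anns: list[Annotation] = []
    for field_name in ("title", "abstract"):
        text = getattr(doc, field_name)
        cands = naive_candidates(term, text)
        cands.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
        last_end = 0
        for start, end, entry_id, class_id in cands:
            if start >= last_end:
                anns.append(
                    Annotation(
                        doc_id=doc.doc_id, field=field_name, start=start, end=end,
                        matched_text=text[start:end], entry_id=entry_id, class_id=class_id,
                    )
                )
                last_end = end
    return anns


# ---------------------------------------------------------------------------
# Small hand-built terminologies
# ---------------------------------------------------------------------------


def build_terminology(classes, entries) -> Terminology:
    """classes: (class_id, name, parent_id); entries: (entry_id, class_id, synonyms)
    where each synonym is text or (text, case_sensitive)."""
    term = Terminology(name="fixture", version="1")
    for cid, name, parent in classes:
        term.classes[cid] = TermClass(class_id=cid, name=name, parent_id=parent)
    for eid, cid, syns in entries:
        built = []
        for s in syns:
            if isinstance(s, tuple):
                built.append(make_synonym(s[0], s[1]))
            else:
                built.append(make_synonym(s))
        term.entries[eid] = TermEntry(
            entry_id=eid, preferred_name=built[0].text, class_id=cid, synonyms=tuple(built)
        )
    term.validate()
    return term


@pytest.fixture
def six_class_terminology() -> Terminology:
    """The six biomarker retrieval classes with a few entries each."""
    classes = [
        ("ClinicalManagement", "Clinical Management", None),
        ("Diagnostics", "Diagnostics", None),
        ("Prognosis", "Prognosis", None),
        ("Statistics", "Statistics", None),
        ("Evidence", "Evidence", None),
        ("Antecedent", "Antecedent", None),
    ]
    entries = [
        ("CM:patient", "ClinicalManagement", ["patient", "cohort study"]),
        ("DX:ihc", "Diagnostics", ["immunohistochemistry"]),
        ("PR:outcome", "Prognosis", ["clinical response", "biomarker"]),
        ("ST:km", "Statistics", ["Kaplan-Meier Analysis", "univariate analysis"]),
        ("EV:expr", "Evidence", ["expression"]),
        ("EV:mut", "Evidence", ["mutation", "polymorphism"]),
        ("EV:amp", "Evidence", ["gene amplification"]),
        ("AN:smoke", "Antecedent", ["smoker", "exposure"]),
    ]
    return build_terminology(classes, entries)


@pytest.fixture
def three_level_terminology() -> Terminology:
    """1 root, 2 children, 4 grandchildren; one entry per class."""
    classes = [
        ("root", "Root", None),
        ("c1", "Child 1", "root"),
        ("c2", "Child 2", "root"),
        ("g11", "Grandchild 11", "c1"),
        ("g12", "Grandchild 12", "c1"),
        ("g21", "Grandchild 21", "c2"),
        ("g22", "Grandchild 22", "c2"),
    ]
    entries = [
        (f"E:{cid}", cid, [f"term{cid}x"]) for cid, _, _ in classes
    ]
    return build_terminology(classes, entries)


def make_docs(texts: dict[str, str]) -> list[Document]:
    return [Document(doc_id=d, title="", abstract=t) for d, t in texts.items()]
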