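"""Corpus parsing, document storage, and document-frequency posting lists.

Documents come from either MEDLINE field-tag text (PMID-/TI-/AB-/DP- tags
with continuation-line unfolding) or JSONL (one object per line with
id/title/abstract and an optional date).  The index maps every terminology
entry and class to the sorted set of documents that mention it at least once
— document frequency, not mention frequency, is the unit throughout, because
both the frequency ranking and the relative-entropy score are defined on
numbers of abstracts.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .annotate import Annotation, Document

__all__ = [
    "CorpusIndex",
    "EntityCorpusStats",
    "CorpusParseError",
    "read_corpus",
    "build_index",
    "entity_stats",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1


class CorpusParseError(ValueError):
    pass


@dataclass
class EntityCorpusStats:
    """Document counts for one entity in a selected and a reference corpus."""

    entry_id: str
    n_sel: int
    N_sel: int
    n_ref: int
    N_ref: int


class CorpusIndex:
    """Document store plus per-entity and per-class posting lists."""

    def __init__(
        self,
        documents: dict[str, Document],
        postings_entry: dict[str, list[str]],
        postings_class: dict[str, list[str]],
    ):
        self.documents = documents
        self.postings_entry = postings_entry
        self.postings_class = postings_class

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def doc_ids(self) -> set[str]:
        return set(self.documents)

    def entry_postings(self, entry_id: str) -> set[str]:
        return set(self.postings_entry.get(entry_id, ()))

    def class_postings(self, class_id: str) -> set[str]:
        return set(self.postings_class.get(class_id, ()))

    def subset(self, doc_ids: Iterable[str]) -> "CorpusIndex":
        """Restriction of the index to *doc_ids* (a selected sub-corpus)."""
        keep = set(doc_ids)
        unknown = keep - set(self.documents)
        if unknown:
            raise KeyError(f"doc_ids not in index: {sorted(unknown)[:5]}")
        docs = {d: self.documents[d] for d in keep}
        pe = {
            e: [d for d in ids if d in keep]
            for e, ids in self.postings_entry.items()
        }
        pc = {
            c: [d for d in ids if d in keep]
            for c, ids in self.postings_class.items()
        }
        return CorpusIndex(docs, {e: v for e, v in pe.items() if v}, {c: v for c, v in pc.items() if v})


# ---------------------------------------------------------------------------
# Corpus readers
# ---------------------------------------------------------------------------

_MEDLINE_TAG = re.compile(r"^([A-Z]{2,4}) *- (.*)$")


def _parse_medline(text: str) -> list[Document]:
    # Records are separated by blank lines; a continuation line is indented
    # (conventionally six spaces) and unfolds into the previous tag with a
    # single joining space.
    docs: list[Document] = []
    record: dict[str, str] = {}
    last_tag: Optional[str] = None
    rec_index = 0

    def flush() -> None:
        nonlocal record, last_tag, rec_index
        if not record:
            return
        rec_index += 1
        if "PMID" not in record:
            raise CorpusParseError(f"record {rec_index} lacks a PMID field")
        docs.append(
            Document(
                doc_id=record["PMID"].strip(),
                title=record.get("TI", ""),
                abstract=record.get("AB", ""),
                date=record.get("DP") or None,
            )
        )
        record = {}
        last_tag = None

    for line in text.splitlines():
        if not line.strip():
            flush()
            continue
        m = _MEDLINE_TAG.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            last_tag = tag
            if tag in record:
                record[tag] = record[tag] + " " + value
            else:
                record[tag] = value
        elif line.startswith(" ") and last_tag is not None:
            record[last_tag] = record[last_tag] + " " + line.strip()
        # anything else is ignored (unrecognized free text)
    flush()
    return docs


def _parse_jsonl(text: str) -> list[Document]:
    docs: list[Document] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusParseError(f"line {lineno}: malformed JSON ({exc})") from exc
        if "id" not in obj:
            raise CorpusParseError(f"line {lineno}: record lacks 'id'")
        if "abstract" not in obj:
            logger.warning("line %d: record %r lacks 'abstract'; using empty text", lineno, obj["id"])
        docs.append(
            Document(
                doc_id=str(obj["id"]),
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                date=obj.get("date"),
            )
        )
    return docs


def read_corpus(path, format: str) -> list[Document]:
    """Read a corpus file; *format* is ``"medline_txt"`` or ``"jsonl"``."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if format == "medline_txt":
        return _parse_medline(text)
    if format == "jsonl":
        return _parse_jsonl(text)
    raise ValueError(f"unsupported corpus format {format!r}")


# ---------------------------------------------------------------------------
# Index construction
# ---------------------------------------------------------------------------


def build_index(docs: list[Document], anns: list[Annotation]) -> CorpusIndex:
    """Build posting lists from documents plus their annotations.

    A document enters an entity's posting list at most once no matter how
    many mentions it holds.  Raises on annotations whose doc_id is unknown.
    """
    documents = {d.doc_id: d for d in docs}
    if len(documents) != len(docs):
        raise CorpusParseError("duplicate doc_id in corpus")
    pe: dict[str, set[str]] = {}
    pc: dict[str, set[str]] = {}
    for ann in anns:
        if ann.doc_id not in documents:
            raise KeyError(f"annotation references unknown doc_id {ann.doc_id!r}")
        pe.setdefault(ann.entry_id, set()).add(ann.doc_id)
        pc.setdefault(ann.class_id, set()).add(ann.doc_id)
    return CorpusIndex(
        documents,
        {e: sorted(ids) for e, ids in pe.items()},
        {c: sorted(ids) for c, ids in pc.items()},
    )


def entity_stats(index_sel: CorpusIndex, index_ref: CorpusIndex, entry_id: str) -> EntityCorpusStats:
    """Per-entity document counts in a selected and a reference corpus."""
    return EntityCorpusStats(
        entry_id=entry_id,
        n_sel=len(index_sel.entry_postings(entry_id)),
        N_sel=index_sel.n_docs,
        n_ref=len(index_ref.entry_postings(entry_id)),
        N_ref=index_ref.n_docs,
    )


# ---------------------------------------------------------------------------
# Persistence (versioned JSON)
# ---------------------------------------------------------------------------


def save_index(index: CorpusIndex, path) -> None:
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "documents": [
            {
                "id": d.doc_id,
                "title": d.title,
                "abstract": d.abstract,
                "date": d.date,
            }
            for d in sorted(index.documents.values(), key=lambda d: d.doc_id)
        ],
        "postings_entry": {e: index.postings_entry[e] for e in sorted(index.postings_entry)},
        "postings_class": {c: index.postings_class[c] for c in sorted(index.postings_class)},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=0, sort_keys=True)


def load_index(path) -> CorpusIndex:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != INDEX_FORMAT_VERSION:
        raise CorpusParseError(f"unsupported index format version {payload.get('format_version')!r}")
    docs = {
        rec["id"]: Document(
            doc_id=rec["id"], title=rec["title"], abstract=rec["abstract"], date=rec.get("date")
        )
        for rec in payload["documents"]
    }
    return CorpusIndex(docs, payload["postings_entry"], payload["postings_class"])


# ---------------------------------------------------------------------------
# Lenient date handling (year required; month/day optional)
# ---------------------------------------------------------------------------

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}
_YEAR = re.compile(r"\b(\d{4})\b")
_DAY = re.compile(r"\b(\d{1,2})\b")


def date_key(date: Optional[str]) -> tuple[int, int, int]:
    """Sortable (year, month, day) from a lenient date string; unknowns are 0.

    Accepts ISO-like strings ("2012-12-18") and MEDLINE DP strings
    ("2012 Dec 18"); a missing or unparseable date sorts before everything.
    """
    if not date:
        return (0, 0, 0)
    year = 0
    m = _YEAR.search(date)
    if m:
        year = int(m.group(1))
        rest = date[: m.start()] + date[m.end():]
    else:
        return (0, 0, 0)
    month = 0
    low = rest.lower()
    for name, num in _MONTHS.items():
        if name in low:
            month = num
            low = low.replace(name, " ", 1)
            break
    if not month:
        m2 = re.search(r"[-/](\d{1,2})", rest)
        if m2:
            month = int(m2.group(1))
            rest = rest[: m2.start()] + rest[m2.end():]
            low = rest.lower()
    day = 0
    m3 = _DAY.search(low)
    if m3:
        cand = int(m3.group(1))
        if 1 <= cand <= 31:
            day = cand
    return (year, month, day)
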