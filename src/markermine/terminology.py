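"""Hierarchical retrieval terminologies: entity classes, entries and synonyms.

A terminology is a forest of named entity classes (e.g. the six biomarker
retrieval classes Clinical Management, Diagnostics, Prognosis, Statistics,
Evidence and Antecedent), each holding dictionary entries with one or more
surface synonyms.  Synonyms carry a case policy so that short, acronym-like
forms ("MS", "APP") are only matched case-sensitively while longer terms
match case-insensitively.

The single native on-disk format is a small TSV dialect (see
:func:`load_terminology`); licensed vocabularies such as MeSH or UMLS are not
parsed directly, but hand-converted subsets fit the dialect.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ACRONYM_THRESHOLD",
    "Synonym",
    "TermClass",
    "TermEntry",
    "Terminology",
    "TerminologyError",
    "StructuralError",
    "CycleError",
    "ReferenceError_",
    "LookupError_",
    "MergeConflictError",
    "make_synonym",
    "load_terminology",
    "loads_terminology",
    "write_terminology",
    "dumps_terminology",
    "subtree",
    "entries_in",
    "merge",
    "stats",
]

#: Synonyms strictly shorter than this many characters default to
#: case-sensitive matching unless the terminology file overrides the policy.
ACRONYM_THRESHOLD = 5


class TerminologyError(ValueError):
    """Base class for terminology validation and parsing failures."""


class StructuralError(TerminologyError):
    """Duplicate identifiers or malformed records."""


class CycleError(TerminologyError):
    """Parent links contain a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("cycle in class parent links: " + " -> ".join(cycle))


class ReferenceError_(TerminologyError):
    """A parent_id or class_id does not resolve."""


class LookupError_(TerminologyError):
    """An operation was asked about an unknown class_id."""


class MergeConflictError(TerminologyError):
    """Two terminologies disagree on the parent of the same class."""


_WS = re.compile(r"\s+")


def _norm_ws(text: str) -> str:
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class Synonym:
    """A surface form with its case policy."""

    text: str
    case_sensitive: bool


def make_synonym(text: str, case_sensitive: Optional[bool] = None) -> Synonym:
    """Build a synonym, applying the acronym default when no policy is given.

    ``case_sensitive=None`` means "use the default policy": forms shorter
    than :data:`ACRONYM_THRESHOLD` characters are case-sensitive, longer
    forms are case-insensitive.  An explicit flag always wins.
    """
    text = _norm_ws(text)
    if not text:
        raise StructuralError("synonym empty after whitespace normalization")
    if case_sensitive is None:
        case_sensitive = len(text) < ACRONYM_THRESHOLD
    return Synonym(text=text, case_sensitive=case_sensitive)


@dataclass(frozen=True)
class TermClass:
    class_id: str
    name: str
    parent_id: Optional[str] = None
    description: str = ""


@dataclass(frozen=True)
class TermEntry:
    entry_id: str
    preferred_name: str
    class_id: str
    synonyms: tuple[Synonym, ...]

    def __post_init__(self):
        # canonical synonym order makes entries independent of declaration
        # (and file line) order
        object.__setattr__(
            self,
            "synonyms",
            tuple(sorted(set(self.synonyms), key=lambda s: (s.text, s.case_sensitive))),
        )


@dataclass
class Terminology:
    """A validated forest of classes plus their dictionary entries."""

    name: str = "terminology"
    version: str = "1"
    classes: dict[str, TermClass] = field(default_factory=dict)
    entries: dict[str, TermEntry] = field(default_factory=dict)

    def validate(self) -> None:
        """Check all structural invariants; raise a TerminologyError otherwise."""
        for cid, cls in self.classes.items():
            if cls.class_id != cid:
                raise StructuralError(f"class key {cid!r} != class_id {cls.class_id!r}")
            if cls.parent_id is not None and cls.parent_id not in self.classes:
                raise ReferenceError_(
                    f"class {cid!r}: parent {cls.parent_id!r} does not resolve"
                )
        _check_forest(self.classes)
        for eid, entry in self.entries.items():
            if entry.entry_id != eid:
                raise StructuralError(f"entry key {eid!r} != entry_id {entry.entry_id!r}")
            if entry.class_id not in self.classes:
                raise ReferenceError_(
                    f"entry {eid!r}: class {entry.class_id!r} does not resolve"
                )
            if not entry.synonyms:
                raise StructuralError(f"entry {eid!r} has no synonyms")
            for syn in entry.synonyms:
                if not _norm_ws(syn.text):
                    raise StructuralError(f"entry {eid!r}: empty synonym")

    def children(self, class_id: str) -> list[str]:
        return sorted(c.class_id for c in self.classes.values() if c.parent_id == class_id)

    def roots(self) -> list[str]:
        return sorted(c.class_id for c in self.classes.values() if c.parent_id is None)

    def stats(self) -> tuple[int, int, int]:
        return stats(self)


def _check_forest(classes: dict[str, TermClass]) -> None:
    """Reject cycles in parent links (iterative, path-marking DFS)."""
    state: dict[str, int] = {}  # 0 unvisited / 1 on path / 2 done
    for start in classes:
        if state.get(start, 0) == 2:
            continue
        path: list[str] = []
        node: Optional[str] = start
        while node is not None and state.get(node, 0) != 2:
            if state.get(node, 0) == 1:
                i = path.index(node)
                raise CycleError(path[i:] + [node])
            state[node] = 1
            path.append(node)
            node = classes[node].parent_id
        for n in path:
            state[n] = 2


# ---------------------------------------------------------------------------
# TSV dialect
#
#   # comment (ignored; "# name=<n> version=<v>" carries metadata)
#   C <TAB> class_id <TAB> name <TAB> parent_id_or_- <TAB> description
#   S <TAB> entry_id <TAB> class_id <TAB> preferred_name <TAB> synonym <TAB> cs|ci|-
#
# One synonym per S line; '-' in the policy column applies the acronym default.
# ---------------------------------------------------------------------------

_META = re.compile(r"#\s*name=(?P<name>\S+)\s+version=(?P<version>\S+)")


def loads_terminology(text: str, name: str = "terminology") -> Terminology:
    term = Terminology(name=name)
    pending: dict[str, tuple[str, str, list[Synonym]]] = {}  # eid -> (class, pref, syns)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            m = _META.match(line.strip())
            if m:
                term.name = m.group("name")
                term.version = m.group("version")
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "C":
            if len(fields) != 5:
                raise StructuralError(f"line {lineno}: C record needs 5 fields, got {len(fields)}")
            _, cid, cname, parent, desc = fields
            if cid in term.classes:
                raise StructuralError(f"line {lineno}: duplicate class_id {cid!r}")
            term.classes[cid] = TermClass(
                class_id=cid,
                name=cname,
                parent_id=None if parent == "-" else parent,
                description=desc,
            )
        elif kind == "S":
            if len(fields) != 6:
                raise StructuralError(f"line {lineno}: S record needs 6 fields, got {len(fields)}")
            _, eid, cid, pref, syn_text, policy = fields
            if policy == "cs":
                cs: Optional[bool] = True
            elif policy == "ci":
                cs = False
            elif policy == "-":
                cs = None
            else:
                raise StructuralError(f"line {lineno}: case policy must be cs|ci|-, got {policy!r}")
            syn = make_synonym(syn_text, cs)
            if eid in pending:
                p_cid, p_pref, syns = pending[eid]
                if p_cid != cid:
                    raise StructuralError(
                        f"line {lineno}: entry {eid!r} re-declared with class {cid!r} != {p_cid!r}"
                    )
                if syn not in syns:
                    syns.append(syn)
            else:
                pending[eid] = (cid, pref, [syn])
        else:
            raise StructuralError(f"line {lineno}: unknown record type {kind!r}")
    for eid, (cid, pref, syns) in pending.items():
        term.entries[eid] = TermEntry(
            entry_id=eid, preferred_name=pref, class_id=cid, synonyms=tuple(syns)
        )
    term.validate()
    return term


def load_terminology(path, format: str = "tsv") -> Terminology:
    """Read a terminology from *path* in the native TSV dialect.

    The result is independent of the order of C and S lines in the file.
    """
    if format != "tsv":
        raise ValueError(f"unsupported terminology format {format!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    import os

    return loads_terminology(text, name=os.path.splitext(os.path.basename(str(path)))[0])


def dumps_terminology(term: Terminology) -> str:
    """Serialize to the TSV dialect, deterministically (sorted records)."""
    buf = io.StringIO()
    buf.write(f"# name={term.name} version={term.version}\n")
    for cid in sorted(term.classes):
        c = term.classes[cid]
        parent = c.parent_id if c.parent_id is not None else "-"
        buf.write(f"C\t{c.class_id}\t{c.name}\t{parent}\t{c.description}\n")
    for eid in sorted(term.entries):
        e = term.entries[eid]
        for syn in e.synonyms:
            policy = "cs" if syn.case_sensitive else "ci"
            buf.write(f"S\t{e.entry_id}\t{e.class_id}\t{e.preferred_name}\t{syn.text}\t{policy}\n")
    return buf.getvalue()


def write_terminology(term: Terminology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_terminology(term))


# ---------------------------------------------------------------------------
# Navigation and algebra
# ---------------------------------------------------------------------------


def subtree(term: Terminology, class_id: str) -> set[str]:
    """The class itself plus all transitive descendants."""
    if class_id not in term.classes:
        raise LookupError_(f"unknown class_id {class_id!r}")
    children: dict[str, list[str]] = {}
    for c in term.classes.values():
        if c.parent_id is not None:
            children.setdefault(c.parent_id, []).append(c.class_id)
    out: set[str] = set()
    stack = [class_id]
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        stack.extend(children.get(node, ()))
    return out


def entries_in(term: Terminology, class_ids: Iterable[str]) -> set[TermEntry]:
    """Union of entries whose owning class is in *class_ids*."""
    wanted = set(class_ids)
    for cid in wanted:
        if cid not in term.classes:
            raise LookupError_(f"unknown class_id {cid!r}")
    return {e for e in term.entries.values() if e.class_id in wanted}


def merge(base: Terminology, extension: Terminology) -> Terminology:
    """Union of two terminologies.

    Classes are unioned; the same class_id must agree on its parent.  On an
    entry_id collision the synonym lists are unioned with set semantics on
    (text, case_sensitive); the base's preferred name wins.
    """
    out = Terminology(name=base.name, version=base.version)
    out.classes = dict(base.classes)
    for cid, cls in extension.classes.items():
        if cid in out.classes and out.classes[cid].parent_id != cls.parent_id:
            raise MergeConflictError(
                f"class {cid!r}: parent {out.classes[cid].parent_id!r} vs {cls.parent_id!r}"
            )
        out.classes.setdefault(cid, cls)
    out.entries = dict(base.entries)
    for eid, entry in extension.entries.items():
        if eid in out.entries:
            have = out.entries[eid]
            merged = list(have.synonyms)
            for syn in entry.synonyms:
                if syn not in merged:
                    merged.append(syn)
            out.entries[eid] = TermEntry(
                entry_id=eid,
                preferred_name=have.preferred_name,
                class_id=have.class_id,
                synonyms=tuple(merged),
            )
        else:
            out.entries[eid] = entry
    out.validate()
    return out


def stats(term: Terminology) -> tuple[int, int, int]:
    """(n_classes, n_entries, n_synonyms); synonyms count distinct (entry, text) pairs."""
    n_syn = sum(len({s.text for s in e.synonyms}) for e in term.entries.values())
    return (len(term.classes), len(term.entries), n_syn)
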