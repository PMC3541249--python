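"""Entity ranking by document frequency or by relative entropy.

The relative-entropy (Kullback–Leibler information-gain) score of an entity
compares its prevalence in a query-selected corpus with its prevalence in an
unspecific reference corpus:

    RE(p1, p2) = p1 * log(p1 / p2)

In the default ``proportions`` mode, p1 = n_sel / N_sel and
p2 = (n_ref + pseudocount) / (N_ref + pseudocount), where n_sel / n_ref are
the numbers of abstracts containing the entity in the selected / reference
corpus and N_sel / N_ref the corpus sizes.  Entities that are frequent in
the selection but common everywhere score low (the IL1B effect: a cytokine
mentioned in tens of thousands of abstracts is demoted even when frequent in
the disease corpus), while selection-specific entities score high.  A
``raw_counts`` mode substitutes the unnormalized counts for p1 and p2.

Ranking is descending by score with deterministic tie-breaking (higher
selected-corpus count first, then lexicographic entry id).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

from .corpus_index import CorpusIndex, EntityCorpusStats

__all__ = [
    "RankingConfig",
    "RankedEntity",
    "RankedEntityList",
    "relative_entropy",
    "rank_by_frequency",
    "rank_by_relative_entropy",
    "filter_min_docs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankingConfig:
    mode: Literal["frequency", "relative_entropy"] = "relative_entropy"
    proportion_mode: Literal["proportions", "raw_counts"] = "proportions"
    pseudocount: float = 1.0
    min_doc_count: int = 0
    log_base: Literal["natural"] = "natural"

    def __post_init__(self):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.min_doc_count < 0:
            raise ValueError("min_doc_count must be nonnegative")
        # pseudocount = 0 is tolerated at construction; scoring rejects it
        # lazily iff it would divide by a zero reference proportion.


@dataclass(frozen=True)
class RankedEntity:
    rank: int
    entry_id: str
    score: float
    n_sel: int
    n_ref: int


RankedEntityList = list[RankedEntity]


def relative_entropy(stats: EntityCorpusStats, cfg: RankingConfig) -> float:
    """RE = p1 * ln(p1/p2); zero when n_sel = 0 (the 0*log 0 convention)."""
    if stats.N_sel <= 0 or stats.N_ref <= 0:
        raise ValueError("relative entropy needs non-empty selected and reference corpora")
    if stats.n_sel == 0:
        return 0.0
    if cfg.proportion_mode == "proportions":
        p1 = stats.n_sel / stats.N_sel
        p2 = (stats.n_ref + cfg.pseudocount) / (stats.N_ref + cfg.pseudocount)
        if p2 <= 0:
            raise ValueError("zero reference proportion; use a positive pseudocount")
    else:
        p1 = float(stats.n_sel)
        p2 = float(stats.n_ref + cfg.pseudocount)
        if p2 <= 0:
            raise ValueError("raw_counts mode with n_ref + pseudocount = 0")
    return p1 * math.log(p1 / p2)


def _finalize(scored: list[tuple[str, float, int, int]]) -> RankedEntityList:
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [
        RankedEntity(rank=i, entry_id=e, score=s, n_sel=ns, n_ref=nr)
        for i, (e, s, ns, nr) in enumerate(scored, start=1)
    ]


def rank_by_frequency(table: list[tuple[str, int]]) -> RankedEntityList:
    """Descending document-frequency order; score equals the count."""
    for entry_id, count in table:
        if count < 0:
            raise ValueError(f"negative doc_count for {entry_id!r}")
    scored = [(e, float(c), c, 0) for e, c in table if c > 0]
    return _finalize(scored)


def rank_by_relative_entropy(
    table: list[tuple[str, int]],
    ref_index: CorpusIndex,
    sel_size: int,
    cfg: RankingConfig | None = None,
) -> RankedEntityList:
    """Score each table entry against the reference corpus and sort.

    Entities absent from the reference are smoothed (n_ref = 0 plus the
    pseudocount) with a warning; entities with zero selected-corpus count
    are excluded — they are not in the selected corpus at all.
    """
    if sel_size <= 0:
        raise ValueError("sel_size must be positive")
    cfg = cfg or RankingConfig()
    scored: list[tuple[str, float, int, int]] = []
    for entry_id, n_sel in table:
        if n_sel <= 0:
            continue
        n_ref = len(ref_index.entry_postings(entry_id))
        if n_ref == 0:
            logger.warning("entity %r missing from reference corpus; smoothing", entry_id)
        stats = EntityCorpusStats(
            entry_id=entry_id, n_sel=n_sel, N_sel=sel_size, n_ref=n_ref, N_ref=ref_index.n_docs
        )
        scored.append((entry_id, relative_entropy(stats, cfg), n_sel, n_ref))
    return _finalize(scored)


def filter_min_docs(table: list[tuple[str, int]], k: int) -> list[tuple[str, int]]:
    """Drop entries occurring in fewer than *k* documents (boundary inclusive)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return [(e, c) for e, c in table if c >= k]
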