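"""Evaluation battery for dictionary-based biomarker retrieval.

Covers four instruments:

* Cohen's kappa for inter-annotator agreement on a k-category contingency
  table, kappa = (Pr(a) - Pr(e)) / (1 - Pr(e));
* gene-set enrichment of a ranked entity list against a gold standard — a
  running hit count while walking down the list, whose maximum prefix sum is
  the enrichment score (with 0/+1 increments that maximum is the final
  value, so the whole curve is reported alongside the scalar);
* precision / recall / F at every cut-off rank k, where the top-k entities
  are the retrieved positives and the gold standard is the relevant set:
  precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R); rows are
  extracted at recall thresholds (first rank reaching each threshold) and at
  the maximal F;
* top-abstract selection for manual inspection — the most recent documents
  of a result set mentioning a given entity.

A true-negative count is never computed: ranked retrieval over an open
entity universe has no defined negative class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotate import Document
from .corpus_index import CorpusIndex, date_key
from .query import DocSet
from .ranking import RankedEntityList

__all__ = [
    "AgreementTable",
    "GoldStandard",
    "EnrichmentCurve",
    "RetrievalMetrics",
    "load_gold_standard",
    "cohens_kappa",
    "enrichment_curve",
    "enrichment_score",
    "f_score",
    "precision_recall_table",
    "metrics_at_recall",
    "max_f_score",
    "select_top_abstracts",
]

logger = logging.getLogger(__name__)


@dataclass
class AgreementTable:
    """k x k matrix of item counts; cell (i, j) = items labelled category i
    by rater 1 and category j by rater 2."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("agreement table must be square")
        if np.any(self.counts < 0) or not np.all(self.counts == np.round(self.counts)):
            raise ValueError("agreement table holds nonnegative integer counts")

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GoldStandard:
    entity_ids: frozenset[str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.entity_ids)


def load_gold_standard(path, source: str = "") -> GoldStandard:
    """One entity id per line; '#' comments and blank lines ignored."""
    ids: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return GoldStandard(entity_ids=frozenset(ids), source=source or str(path))


@dataclass
class EnrichmentCurve:
    """hits[i-1] = gold-standard entities among the top-i ranked entities."""

    hits: list[int]

    @property
    def final(self) -> int:
        return self.hits[-1] if self.hits else 0


@dataclass(frozen=True)
class RetrievalMetrics:
    rank: int
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f_score: float


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement: (Pr(a) - Pr(e)) / (1 - Pr(e)).

    Pr(a) is the observed agreement (trace / n); Pr(e) the agreement expected
    from the raters' marginal label distributions.  When Pr(e) = 1 the value
    is defined as 1.0 if the observed agreement is also perfect, and is a
    domain error otherwise.
    """
    n = table.n_items
    if n <= 0:
        raise ValueError("empty agreement table")
    counts = table.counts.astype(float)
    pr_a = float(np.trace(counts)) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    pr_e = float(np.dot(row, col))
    if abs(1.0 - pr_e) < 1e-15:
        if abs(1.0 - pr_a) < 1e-15:
            return 1.0
        raise ValueError("chance agreement is 1 with imperfect observed agreement")
    return (pr_a - pr_e) / (1.0 - pr_e)


def enrichment_curve(ranked: RankedEntityList, gold: GoldStandard) -> EnrichmentCurve:
    """Running count of gold-standard hits down the ranked list."""
    if not ranked:
        raise ValueError("ranked list is empty")
    if not gold.entity_ids:
        logger.warning("empty gold standard: enrichment curve is all zeros")
    hits: list[int] = []
    running = 0
    for rec in ranked:
        if rec.entry_id in gold.entity_ids:
            running += 1
        hits.append(running)
    return EnrichmentCurve(hits=hits)


def enrichment_score(curve: EnrichmentCurve) -> int:
    """Maximum prefix sum of the hit increments (= final value here, since
    every increment is 0 or +1)."""
    return max(curve.hits, default=0)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0.0 <= precision <= 1.0) or not (0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_table(ranked: RankedEntityList, gold: GoldStandard) -> list[RetrievalMetrics]:
    """One metrics row per cut-off rank k = 1..N (top-k = retrieved positives)."""
    if not gold.entity_ids:
        raise ValueError("gold standard is empty")
    n_gold = len(gold.entity_ids)
    rows: list[RetrievalMetrics] = []
    tp = 0
    for k, rec in enumerate(ranked, start=1):
        if rec.entry_id in gold.entity_ids:
            tp += 1
        fp = k - tp
        fn = n_gold - tp
        precision = tp / k
        recall = tp / n_gold
        rows.append(
            RetrievalMetrics(
                rank=k, TP=tp, FP=fp, FN=fn,
                precision=precision, recall=recall,
                f_score=f_score(precision, recall),
            )
        )
    return rows


def metrics_at_recall(
    table: list[RetrievalMetrics], thresholds: list[float]
) -> dict[float, RetrievalMetrics | None]:
    """First rank reaching each recall threshold (no interpolation).

    Unreachable thresholds map to None.
    """
    out: dict[float, RetrievalMetrics | None] = {}
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"recall threshold must lie in (0, 1], got {t}")
        hit = next((row for row in table if row.recall >= t), None)
        out[t] = hit
    return out


def max_f_score(table: list[RetrievalMetrics]) -> tuple[int, float]:
    """(rank, F) of the row maximizing F; the earliest rank wins ties."""
    if not table:
        raise ValueError("empty metrics table")
    best = max(table, key=lambda row: (row.f_score, -row.rank))
    return (best.rank, best.f_score)


def select_top_abstracts(
    index: CorpusIndex, docset: DocSet, entry_id: str, n: int
) -> list[Document]:
    """The *n* most recent docset documents mentioning the entity.

    Sorted by date descending then doc_id descending — the manual-inspection
    protocol looks at the first retrieved (most recent) abstracts.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    matching = index.entry_postings(entry_id) & docset.doc_ids
    docs = [index.documents[d] for d in matching]
    docs.sort(key=lambda d: (date_key(d.date), d.doc_id), reverse=True)
    return docs[:n]
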