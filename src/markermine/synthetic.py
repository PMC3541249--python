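"""Seeded synthetic terminologies, corpora and gold standards.

The generator emulates the statistical structure the retrieval method
assumes, without any natural language: documents are sequences of filler
tokens with dictionary synonyms planted at known offsets.  The planted
structure mirrors a disease literature:

* a disease concept mentioned in a configurable fraction of abstracts;
* the six biomarker terminology classes (Clinical Management, Diagnostics,
  Prognosis, Statistics, Evidence, Antecedent), each planted per document
  with its own rate;
* a pool of gene entries whose background mention frequencies follow a
  Zipf-like skew (a few ubiquitous genes, a long tail of rare ones);
* a planted subset of "true marker" genes whose mention probability is
  multiplied by an enrichment factor inside documents that contain both the
  disease term and a Clinical Management or Evidence term — the
  co-occurrence signal the class-filtered queries are designed to exploit.

Filler vocabulary is guaranteed disjoint from every synonym, so the emitted
annotations are the unique ground truth and dictionary matching must
recover them exactly.  All randomness flows from one numpy Generator seeded
by the config, consumed document by document, making corpora, annotations
and downstream metrics fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotate import Annotation, Document, annotate_corpus, compile_matcher
from .corpus_index import CorpusIndex, build_index
from .evaluation import EnrichmentCurve, GoldStandard, enrichment_curve
from .query import evaluate_query, entity_table, parse_query
from .ranking import RankedEntityList, RankingConfig, rank_by_frequency, rank_by_relative_entropy
from .terminology import Terminology, TermClass, TermEntry, make_synonym

__all__ = [
    "BIOMARKER_CLASSES",
    "SyntheticConfig",
    "SyntheticCorpus",
    "RecoveryReport",
    "generate_terminology",
    "generate_corpus",
    "recovery_experiment",
    "marker_rank_separation",
]

#: The six biomarker retrieval classes: (class_id, display name, description).
BIOMARKER_CLASSES: tuple[tuple[str, str, str], ...] = (
    ("ClinicalManagement", "Clinical Management",
     "Terms indicating clinical investigations on patients"),
    ("Diagnostics", "Diagnostics",
     "Terms representing clinical as well as molecular diagnostics"),
    ("Prognosis", "Prognosis",
     "Terms indicating the prediction for a patient or outcome of therapies"),
    ("Statistics", "Statistics",
     "Statistical methods indicating the strength of the biomarker relationship"),
    ("Evidence", "Evidence",
     "Terms describing genetic or molecular evidence for activity of a gene"),
    ("Antecedent", "Antecedent",
     "Terms expressing exposure to hazardous agents and risk factors"),
)

#: Expected planted tokens per document above which the config is rejected.
MAX_EXPECTED_MENTIONS = 200.0


def _default_class_rates() -> dict[str, float]:
    return {
        "ClinicalManagement": 0.5,
        "Diagnostics": 0.3,
        "Prognosis": 0.3,
        "Statistics": 0.2,
        "Evidence": 0.4,
        "Antecedent": 0.1,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    ``enrichment_factor`` multiplies the per-document marker-gene mention
    probability (``marker_rate``) inside documents containing both the
    disease term and a Clinical Management or Evidence term;
    ``enrichment_factor = 1`` is the null corpus with no planted signal.
    """

    seed: int = 0
    n_docs: int = 2000
    n_genes: int = 200
    n_marker_genes: int = 20
    background_gene_skew: float = 1.1
    disease_prevalence: float = 0.3
    class_term_rates: dict[str, float] = field(default_factory=_default_class_rates)
    enrichment_factor: float = 5.0
    marker_rate: float = 0.02
    background_mentions_per_doc: float = 2.0
    terms_per_class: int = 5
    filler_vocab_size: int = 400
    filler_tokens_per_doc: int = 30

    def __post_init__(self):
        if self.n_marker_genes > self.n_genes:
            raise ValueError("n_marker_genes must not exceed n_genes")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        probs = [self.disease_prevalence, self.marker_rate, *self.class_term_rates.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        expected = (
            self.disease_prevalence
            + sum(self.class_term_rates.values())
            + self.background_mentions_per_doc
            + self.n_marker_genes * min(1.0, self.marker_rate * self.enrichment_factor)
        )
        if expected > MAX_EXPECTED_MENTIONS:
            raise ValueError(
                f"config implies ~{expected:.0f} planted mentions per document "
                f"(cap {MAX_EXPECTED_MENTIONS:.0f})"
            )


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    true_annotations: list[Annotation]
    marker_set: GoldStandard
    config: SyntheticConfig


_CONSONANTS = "bcdfghjklmnpqrstvwxz"


def _word(rng: np.random.Generator, length: int) -> str:
    return "".join(_CONSONANTS[i] for i in rng.integers(0, len(_CONSONANTS), size=length))


def generate_terminology(cfg: SyntheticConfig) -> Terminology:
    """Six biomarker classes plus Disease and Genes classes.

    Synonym strings are random (seed-dependent) but the class structure,
    entry ids and counts are identical across seeds.  Every synonym carries
    a distinguishing prefix so filler text can never collide with it.
    """
    rng = np.random.default_rng(cfg.seed)
    term = Terminology(name="synthetic", version="1")
    for cid, name, desc in BIOMARKER_CLASSES:
        term.classes[cid] = TermClass(class_id=cid, name=name, description=desc)
    term.classes["Disease"] = TermClass(
        class_id="Disease", name="Diseases", description="Disease concepts"
    )
    term.classes["Genes"] = TermClass(
        class_id="Genes", name="Human Genes/Proteins", description="Gene and protein entries"
    )
    for cid, _, _ in BIOMARKER_CLASSES:
        prefix = cid.lower()[:4]
        for j in range(cfg.terms_per_class):
            eid = f"{cid}:{j:02d}"
            surface = f"{prefix}q{_word(rng, 6)}"
            term.entries[eid] = TermEntry(
                entry_id=eid, preferred_name=surface, class_id=cid,
                synonyms=(make_synonym(surface),),
            )
    disease_surface = f"morbusq{_word(rng, 6)}"
    term.entries["Disease:00"] = TermEntry(
        entry_id="Disease:00", preferred_name=disease_surface, class_id="Disease",
        synonyms=(make_synonym(disease_surface),),
    )
    for i in range(cfg.n_genes):
        eid = f"GENE{i:04d}"
        surface = f"gnq{_word(rng, 5)}{i:04d}"
        term.entries[eid] = TermEntry(
            entry_id=eid, preferred_name=surface, class_id="Genes",
            synonyms=(make_synonym(surface),),
        )
    term.validate()
    return term


def _zipf_probs(n: int, skew: float) -> np.ndarray:
    weights = 1.0 / np.power(np.arange(1, n + 1, dtype=float), skew)
    return weights / weights.sum()


def generate_corpus(cfg: SyntheticConfig, term: Terminology) -> SyntheticCorpus:
    """Assemble documents with planted mentions and exact gold annotations.

    Per document, in a fixed consumption order of one random stream:
    disease presence, one planted term per biomarker class (per class rate),
    a Poisson number of background gene mentions drawn from the Zipf skew,
    marker-gene mentions (rate boosted by ``enrichment_factor`` in
    disease + Clinical Management/Evidence documents), then the shuffle that
    interleaves planted surfaces with filler tokens.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = sorted(e for e in term.entries if term.entries[e].class_id == "Genes")
    if len(gene_ids) != cfg.n_genes:
        raise ValueError("terminology does not match config (gene count)")
    marker_ids = sorted(rng.choice(gene_ids, size=cfg.n_marker_genes, replace=False).tolist())
    marker_index = set(marker_ids)
    class_entries = {
        cid: sorted(e for e in term.entries if term.entries[e].class_id == cid)
        for cid, _, _ in BIOMARKER_CLASSES
    }
    zipf = _zipf_probs(cfg.n_genes, cfg.background_gene_skew)
    # filler words use a vowel-bearing shape no synonym generator emits
    filler_vocab = [f"w{_word(rng, 4)}a{k}" for k in range(cfg.filler_vocab_size)]

    documents: list[Document] = []
    annotations: list[Annotation] = []
    for i in range(cfg.n_docs):
        planted: list[str] = []  # entry ids, one surface each
        has_disease = rng.random() < cfg.disease_prevalence
        if has_disease:
            planted.append("Disease:00")
        planted_classes: set[str] = set()
        for cid, _, _ in BIOMARKER_CLASSES:
            if rng.random() < cfg.class_term_rates.get(cid, 0.0):
                planted.append(class_entries[cid][int(rng.integers(0, len(class_entries[cid])))])
                planted_classes.add(cid)
        n_bg = int(rng.poisson(cfg.background_mentions_per_doc))
        if n_bg > 0:
            for gi in rng.choice(cfg.n_genes, size=n_bg, p=zipf):
                planted.append(gene_ids[int(gi)])
        enriched = has_disease and bool(planted_classes & {"ClinicalManagement", "Evidence"})
        p_marker = min(1.0, cfg.marker_rate * (cfg.enrichment_factor if enriched else 1.0))
        for mid in marker_ids:
            if rng.random() < p_marker:
                planted.append(mid)

        filler = [filler_vocab[int(k)] for k in rng.integers(0, cfg.filler_vocab_size,
                                                             size=cfg.filler_tokens_per_doc)]
        tokens: list[tuple[str, Optional[str]]] = [(w, None) for w in filler]
        tokens += [(term.entries[eid].preferred_name, eid) for eid in planted]
        order = rng.permutation(len(tokens))
        tokens = [tokens[int(k)] for k in order]

        doc_id = f"D{i:06d}"
        title = " ".join(filler_vocab[int(k)] for k in rng.integers(0, cfg.filler_vocab_size, size=3))
        pieces: list[str] = []
        offset = 0
        for text, eid in tokens:
            if pieces:
                offset += 1  # joining space
            start = offset
            pieces.append(text)
            offset += len(text)
            if eid is not None:
                annotations.append(
                    Annotation(
                        doc_id=doc_id, field="abstract", start=start, end=offset,
                        matched_text=text, entry_id=eid,
                        class_id=term.entries[eid].class_id,
                    )
                )
        date = f"{2000 + (i % 13)}-{1 + (i % 12):02d}-{1 + (i % 28):02d}"
        documents.append(Document(doc_id=doc_id, title=title, abstract=" ".join(pieces), date=date))

    annotations.sort(key=lambda a: (a.doc_id, a.field, a.start))
    return SyntheticCorpus(
        documents=documents,
        true_annotations=annotations,
        marker_set=GoldStandard(entity_ids=frozenset(marker_ids), source="planted markers"),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# End-to-end recovery experiment
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Full-pipeline outcome on one synthetic corpus.

    Curves compare the class-filtered query (disease AND Genes AND
    Clinical Management AND Evidence) with the unfiltered baseline (disease
    AND Genes), both ranked by relative entropy against the whole synthetic
    corpus as reference, and evaluated against the planted marker set.
    """

    valid: bool
    config: SyntheticConfig
    n_unfiltered_docs: int = 0
    n_filtered_docs: int = 0
    ranked_unfiltered: RankedEntityList = field(default_factory=list)
    ranked_filtered: RankedEntityList = field(default_factory=list)
    curve_unfiltered: Optional[EnrichmentCurve] = None
    curve_filtered: Optional[EnrichmentCurve] = None
    marker_top_decile_fraction: float = 0.0
    dominance_margin: int = 0
    mean_reciprocal_rank_markers: float = 0.0
    mean_reciprocal_rank_nonmarkers: float = 0.0
    marker_set: Optional[GoldStandard] = None


def _curve_at(curve: EnrichmentCurve, i: int) -> int:
    """curve value at 1-based rank i, held constant past the list end."""
    if not curve.hits:
        return 0
    return curve.hits[min(i, len(curve.hits)) - 1]


def recovery_experiment(cfg: SyntheticConfig, ranking_cfg: RankingConfig | None = None) -> RecoveryReport:
    """Run the whole pipeline on a generated corpus and score marker recovery.

    Steps: generate -> dictionary-annotate -> index -> evaluate the
    unfiltered and class-filtered Boolean queries -> entity tables -> rank
    by relative entropy -> enrichment curves against the planted markers.
    """
    if cfg.n_marker_genes == 0:
        return RecoveryReport(valid=False, config=cfg)
    term = generate_terminology(cfg)
    corpus = generate_corpus(cfg, term)
    matcher = compile_matcher(term)
    anns = annotate_corpus(matcher, corpus.documents)
    index = build_index(corpus.documents, anns)

    disease_name = term.entries["Disease:00"].preferred_name
    q_unfiltered = parse_query(f'"{disease_name}" AND [Genes]', term)
    q_filtered = parse_query(
        f'"{disease_name}" AND [Genes] AND [ClinicalManagement] AND [Evidence]', term
    )
    ds_unfiltered = evaluate_query(index, q_unfiltered, term)
    ds_filtered = evaluate_query(index, q_filtered, term)

    ranking_cfg = ranking_cfg or RankingConfig()
    ranked = {}
    for label, ds in (("unfiltered", ds_unfiltered), ("filtered", ds_filtered)):
        table = entity_table(index, ds, "Genes", term)
        if ranking_cfg.mode == "frequency":
            ranked[label] = rank_by_frequency(table)
        else:
            ranked[label] = rank_by_relative_entropy(table, index, len(ds), ranking_cfg)

    gold = corpus.marker_set
    curve_u = enrichment_curve(ranked["unfiltered"], gold) if ranked["unfiltered"] else EnrichmentCurve([])
    curve_f = enrichment_curve(ranked["filtered"], gold) if ranked["filtered"] else EnrichmentCurve([])

    top_decile = max(1, int(np.ceil(cfg.n_genes / 10)))
    marker_ranks = {
        rec.entry_id: rec.rank for rec in ranked["filtered"] if rec.entry_id in gold.entity_ids
    }
    in_top = sum(1 for r in marker_ranks.values() if r <= top_decile)
    frac = in_top / cfg.n_marker_genes

    margin = min(
        (_curve_at(curve_f, i) - _curve_at(curve_u, i) for i in range(1, cfg.n_marker_genes + 1)),
        default=0,
    )

    def mrr(ids: set[str], rankedlist: RankedEntityList) -> float:
        ranks = [1.0 / rec.rank for rec in rankedlist if rec.entry_id in ids]
        missing = len(ids) - len(ranks)
        return (sum(ranks) + 0.0 * missing) / len(ids) if ids else 0.0

    nonmarkers = {e for e in (rec.entry_id for rec in ranked["filtered"])} - gold.entity_ids

    return RecoveryReport(
        valid=True,
        config=cfg,
        n_unfiltered_docs=len(ds_unfiltered),
        n_filtered_docs=len(ds_filtered),
        ranked_unfiltered=ranked["unfiltered"],
        ranked_filtered=ranked["filtered"],
        curve_unfiltered=curve_u,
        curve_filtered=curve_f,
        marker_top_decile_fraction=frac,
        dominance_margin=int(margin),
        mean_reciprocal_rank_markers=mrr(set(gold.entity_ids), ranked["filtered"]),
        mean_reciprocal_rank_nonmarkers=mrr(nonmarkers, ranked["filtered"]),
        marker_set=gold,
    )


def marker_rank_separation(report: RecoveryReport) -> float:
    """One-sided Mann–Whitney p-value that planted markers rank higher
    (smaller rank numbers) than non-markers in the class-filtered ranking.

    Under the null corpus (enrichment_factor = 1) markers are exchangeable
    with non-markers, so this p-value is uniform; with a real planted signal
    it collapses toward zero.
    """
    from scipy.stats import mannwhitneyu

    if not report.valid or report.marker_set is None:
        raise ValueError("invalid recovery report")
    markers = report.marker_set.entity_ids
    mranks = [r.rank for r in report.ranked_filtered if r.entry_id in markers]
    oranks = [r.rank for r in report.ranked_filtered if r.entry_id not in markers]
    if not mranks or not oranks:
        raise ValueError("degenerate ranking: need both marker and non-marker ranks")
    return float(mannwhitneyu(mranks, oranks, alternative="less").pvalue)
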