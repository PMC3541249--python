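# Methods

## The retrieval model

`markermine` treats biomarker literature search as Boolean set algebra over
an entity-annotated corpus followed by statistical ranking of the retrieved
entities.

**Terminology.**  A terminology is a forest of entity classes, each holding
dictionary entries with one or more surface synonyms.  The shipped class
inventory for biomarker retrieval is the six-class scheme — Clinical
Management, Diagnostics, Prognosis, Statistics, Evidence, Antecedent — with
genes/proteins and diseases as further class trees.  Hierarchy is a forest
(one parent per class), not a DAG: queries select either a single class or
a whole subtree, and subtree selection includes the node's own entries plus
all descendants' entries.

**Dictionary matching.**  Annotation is deterministic dictionary NER.  A
match must be flanked by non-alphanumeric characters or string edges
(underscore counts as a boundary, so `MS` never fires inside `MSH2` but
does match `MS_2`).  Case-insensitive synonyms match under Unicode case
folding; synonyms shorter than 5 characters default to case-sensitive
(acronym policy) unless a terminology file overrides it.  Runs of
whitespace and hyphens count as one separator on both sides, so
`Kaplan Meier` matches `Kaplan-Meier`.  Overlaps are resolved greedily
leftmost-longest in a single pass; among candidates covering the identical
span the lexicographically smallest entry id wins.  The production matcher
compiles all synonyms into one alternation regex (longest normalized
pattern first); its contract is extensional identity with the naive
scan-every-synonym oracle, asserted by property tests on random documents
and by the acceptance script on freshly generated ones.

**Index.**  The unit of counting is document frequency: a document enters
an entity's posting list once, however many mentions it holds.  Mention
frequency was considered and rejected because both ranking statistics are
defined on numbers of abstracts.  The reference corpus is any index the
caller designates; nothing is ever downloaded.

**Queries.**  `NOT` > `AND` > `OR`, parentheses group.  A quoted name
resolves to a dictionary entry (preferred name or synonym) and falls back
to a class; `[Brackets]` force class resolution; bare words are free-text
tokens, token-bounded and case-insensitive, with a trailing `*` for prefix
matching (the supported subset of wildcard search).  `NOT` is a
closed-world complement against the evaluated index's document set — the
only testable choice.  On a name that is simultaneously an entry and a
class, the entry wins and a warning is logged.

## Ranking

Relative entropy of an entity is the Kullback–Leibler information-gain term

    RE(p1, p2) = p1 * log(p1 / p2),   natural log.

Two readings of p1/p2 are implemented because the defining description is
ambiguous between corpus proportions and raw abstract counts:

* `proportions` (default): p1 = n_sel/N_sel, p2 = (n_ref + c)/(N_ref + c)
  with pseudocount c = 1.  This is the true information-gain contribution
  and reproduces the qualitative behaviour that motivated the statistic
  (entities ubiquitous in the reference are demoted despite high selected
  frequency); the pseudocount admits entities absent from the reference.
* `raw_counts`: p1 = n_sel, p2 = n_ref + c, faithful to the literal
  wording.  Published example ranks cannot disambiguate the two without
  the original reference corpus, so both stay available in
  `RankingConfig` rather than guessing.

Conventions: n_sel = 0 scores 0 (0·log 0 = 0) and such entities are
excluded from ranked output entirely; empty selected or reference corpora
are domain errors; the log base does not affect ranks (positive scaling),
which a test asserts by re-scoring in base 2, so no base option is exposed.
Ties break by higher selected-corpus count, then lexicographic entry id;
ranks are consecutive from 1.  Frequency ranking sorts by document count
with the same tie rule.  `filter_min_docs(table, k)` keeps entries with
count ≥ k (boundary inclusive), mirroring the practice of ignoring genes
mentioned in fewer than 5 abstracts when shortlisting candidates.

## Evaluation battery

* **Cohen's kappa** on a k×k agreement table: (Pr(a) − Pr(e))/(1 − Pr(e));
  Pr(e) = 1 with perfect observed agreement is defined as 1.0, otherwise a
  domain error.  Cross-checked against scikit-learn on label vectors.
* **Enrichment**: walking down the ranked list L, the running count of
  entities in the gold set S.  With 0/+1 increments the maximum prefix sum
  equals the final value |L ∩ S|, so the scalar enrichment score is
  reported alongside the whole curve — the curve is what comparative
  enrichment plots actually show.
* **Precision/recall/F**: at every cut-off rank k the top-k entities are
  the retrieved positives, so TP + FP = k and TP + FN = |S|;
  F = 2PR/(P + R), defined as 0 at P = R = 0.  Rows are reported at recall
  thresholds (first rank with recall ≥ t, no interpolation — reported
  absent when unreachable) and at the maximal F (earliest rank on ties).
  True negatives are never computed: ranked retrieval over an open entity
  universe has no defined negative class.
* **Top-abstract selection**: the n most recent documents of a result set
  mentioning an entity (date descending, then doc id descending; lenient
  date parsing needs only a year), supporting manual-inspection protocols
  that read the first ten retrieved abstracts.

The bundled benchmark table of (rank, recall, precision, F) rows is kept as
fixture data in the tests and the acceptance script.  Its printed P, R and
F were evidently rounded to two decimals independently of each other, so
recomputing F from the printed P and R reproduces the printed F only within
the propagated rounding uncertainty (first-order bound
0.005·(∂F/∂P + ∂F/∂R) + 0.005, largest observed discrepancy 0.0104 at
P = 0.92, R = 0.10); the suite asserts exactly that bound on all 32 rows.

## Synthetic corpora

The generator emulates the corpus structure the method assumes and nothing
more: documents are sequences of filler tokens (vocabulary guaranteed
disjoint from every synonym) with dictionary surfaces planted at recorded
offsets, so the emitted annotations are the unique ground truth and
annotation must recover them with precision = recall = 1.  Defaults, chosen
as a realistic small disease literature and fixed before any evaluation:

| parameter | default | meaning |
|---|---|---|
| n_docs | 2000 | abstracts per corpus |
| n_genes | 200 | gene entries |
| n_marker_genes | 20 | planted true markers |
| background_gene_skew | 1.1 | Zipf exponent of background gene mentions |
| background_mentions_per_doc | 2.0 | Poisson mean of background gene slots |
| disease_prevalence | 0.3 | fraction of abstracts mentioning the disease |
| class_term_rates | CM .5, Dx .3, Pr .3, St .2, Ev .4, An .1 | per-document class-term probability |
| marker_rate | 0.02 | baseline per-document marker mention probability |
| enrichment_factor | 5 | marker-rate multiplier in disease + CM/Ev documents |

A single numpy Generator seeded by the config drives everything in a fixed
per-document consumption order (disease → class terms → background genes →
markers → shuffle), giving byte-identical corpora per seed within this
implementation.  Titles contain filler only; all plants go into abstracts.
Document dates cycle deterministically through 2000–2012.

What the generator does **not** model: natural language (grammar is
irrelevant to dictionary NER and set algebra), ambiguous or nested gene
names, abbreviation definitions, corpus growth over time, and any
disease-specific behaviour of the Antecedent class.  Passing tests
therefore demonstrate correctness of the machinery and recoverability of a
planted co-occurrence signal — not NER accuracy on real prose.

## Recovery experiment and calibration

`recovery_experiment` runs generate → annotate → index → query → rank →
enrich.  The unfiltered query is *disease AND [Genes]*; the filtered query
adds *AND [ClinicalManagement] AND [Evidence]*.  Both entity tables are
ranked by relative entropy against the full synthetic corpus as reference
and evaluated against the planted marker set.

Pass thresholds for the recovery tests were frozen from a 25-seed
calibration run at the default conditions before being asserted:

* enrichment factor 5 — top-decile marker fraction (decile of the
  n_genes universe, i.e. top 20 ranks) ranged 0.80–1.00; the pointwise
  filtered-minus-unfiltered curve margin over the first 20 ranks never
  fell below −4 hits; marker/non-marker Mann–Whitney rank separation
  rejected at p < 0.01 on 25/25 seeds.
* enrichment factor 1 (null) — top-decile fraction ranged 0.05–0.35;
  separation rejected on 0/25 seeds.

The frozen assertions are: majority (> 0.5) of markers in the top decile,
curve margin ≥ −5, separation p < 0.01 under enrichment; under the null, no
marker majority and at most one rejection in eight seeds (expected type-I
count 0.08 at α = 0.01).  The curves need not strictly dominate because the
unfiltered disease query already contains every enriched document — the
filter's value is concentration (549 → 100 abstracts at seed 1), not a
larger hit count; the tolerance of 5 hits covers the sampling noise of that
comparison.  Problem sizes throughout (2000 documents, 200 genes, 100
random oracle documents, 50 random query ASTs, 8 null seeds) keep any
single suite run in seconds while leaving the statistics well-powered.

## Numerical and degenerate-input choices

* Rounding for comparisons against two-decimal published values:
  round-half-up at two decimals.
* Pseudocount 1 on the reference side only; the selected corpus is never
  smoothed (an entity absent from the selection is simply not ranked).
* Empty terminology compiles to a matcher that matches nothing (warning).
* Empty gold standards give all-zero enrichment curves with a warning;
  empty agreement tables, empty metric tables and non-positive corpus
  sizes are errors.
* JSONL records without an abstract get empty text with a warning; MEDLINE
  records without a PMID are parse errors.
* Merge unions synonym sets on entry-id collisions ((text, case-policy)
  set semantics, base's preferred name wins) and rejects classes whose
  parents disagree.
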