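# markermine

Dictionary-based retrieval of biomarker information from biomedical
abstracts.

Finding candidate biomarkers for a disease in the literature is mostly a
retrieval problem: abstracts that report useful biomarker evidence tend to
mention a gene or protein **together with** terms about clinical management
of patients, molecular evidence of alteration (expression changes,
mutations, SNPs), diagnostics, prognosis, or statistics.  `markermine`
implements that idea as a reusable toolkit for anyone building or studying
semantic literature search over entity-annotated corpora:

* **hierarchical terminologies** — entity classes (the six biomarker
  retrieval classes *Clinical Management*, *Diagnostics*, *Prognosis*,
  *Statistics*, *Evidence*, *Antecedent*, plus genes and diseases) holding
  dictionary entries with case-policy-aware synonyms, in a plain TSV format;
* **deterministic dictionary NER** — token-bounded, spelling-variant-folding
  matching of every synonym in titles and abstracts, with leftmost-longest
  overlap resolution, verified span-for-span against a naive oracle;
* **an inverted index** of document-frequency posting lists per entity and
  per class, built from MEDLINE field-tag or JSONL corpora;
* **Boolean class-combination queries** — `"disease" AND [Genes] AND
  [Evidence]` style, with `NOT`/`AND`/`OR`, parentheses, class subtrees and
  free-text tokens;
* **entity ranking** by document frequency or by relative entropy
  (Kullback–Leibler information gain),

  RE(p₁, p₂) = p₁ · log(p₁ / p₂),

  where p₁ is the entity's prevalence in the query-selected corpus and p₂
  its prevalence in an unspecific reference corpus — entities common
  everywhere (cytokines, housekeeping genes) are demoted even when frequent
  in the selection;
* **evaluation instruments** — Cohen's kappa for annotator agreement,
  GSEA-style enrichment curves of a ranked gene list against a gold
  standard, precision/recall/F tables at recall thresholds and the maximal
  F-score (F = 2PR/(P+R)), and most-recent-abstract selection for manual
  inspection;
* **a seeded synthetic-corpus generator** that plants disease, class-term
  and gene mentions (Zipf-skewed background, enriched marker–context
  co-occurrence) with exact ground-truth annotations, so the entire
  pipeline is testable without any external corpus.

## Worked example

Run the full pipeline on a synthetic disease corpus (2000 abstracts, 200
genes of which 20 are planted "true markers", marker mentions 5× more likely
in abstracts containing the disease plus a Clinical Management or Evidence
term):

```python
from markermine import SyntheticConfig, recovery_experiment, marker_rank_separation

rep = recovery_experiment(SyntheticConfig(seed=1))
print(rep.n_unfiltered_docs)             # 549
print(rep.n_filtered_docs)               # 100
print(rep.marker_top_decile_fraction)    # 0.95
print(f"{marker_rank_separation(rep):.3g}")   # 1.47e-11
print(rep.curve_filtered.hits[:10])      # [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
```

The baseline query *disease AND [Genes]* retrieves 549 abstracts; adding
`AND [ClinicalManagement] AND [Evidence]` narrows it to 100.  Ranking the
genes of the filtered set by relative entropy places 95 % of the planted
markers in the top decile of the 200-gene universe, the first ten ranks are
all markers (the enrichment curve climbs 1, 2, …, 10), and a Mann–Whitney
test separates marker from non-marker ranks at p ≈ 10⁻¹¹.  On a null corpus
(enrichment factor 1) the same statistics collapse to chance.

The same pipeline is scriptable from the shell:

```
markermine simulate --seed 5 --out-dir sim/
markermine annotate --terminology sim/terminology.tsv --corpus sim/corpus.jsonl --out ann.jsonl
markermine index --corpus sim/corpus.jsonl --annotations ann.jsonl --out index.json
markermine query --index index.json --terminology sim/terminology.tsv \
    --query '"<disease name>" AND [Genes]' --table-class Genes --out table.tsv
markermine rank --index index.json --table table.tsv --mode entropy --out ranked.tsv
markermine evaluate --ranked ranked.tsv --gold sim/gold.txt --out metrics.tsv
```

Classic worked values of the statistics themselves:
`f_score(0.52, 0.67)` → 0.5855 (0.59 at two decimals) and
`cohens_kappa` of the 2×2 table [[5, 1], [1, 3]] → 0.5833.

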