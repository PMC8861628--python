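# kgemr — knowledge-graph enrichment of EMR vector models

`kgemr` is a research pipeline for a question that comes up whenever
machine learning meets primary-care records: **does injecting concepts from
biomedical and cross-domain knowledge graphs into a text representation of
electronic medical records (EMRs) improve the prediction of
hospitalization?**  It is aimed at biostatisticians and clinical-NLP
researchers who want a tested, fully reproducible implementation of the
whole chain — from record aggregation to the paired statistics — that runs
end-to-end on synthetic data, with no access to any private cohort.

## The model

Each patient *i* is represented by the concatenation of two sparse count
vectors,

> x<sup>i</sup> = V<sup>i</sup> ⊕ C<sup>i</sup>,

where V<sup>i</sup> is a field-prefixed bag-of-words over the aggregated
record text (for hospitalized patients, only consultations *before* the
hospitalization contribute; prefixes keep `personal history: diabetes`
distinct from `family history: diabetes`), and C<sup>i</sup> is a
bag-of-concepts extracted from five knowledge sources:

* **ATC** drug hierarchy — super classes of prescribed drug codes at chosen
  depth levels (`+c1`, `+c2`, `+c1-2`);
* **ICPC-2** — the single super class of each coded health problem (`+t`);
* **NDF-RT** — property–concept drug relations `may_treat`, `may_prevent`,
  `CI_with`, reached through UMLS CUI cross-links (`+d_treat`,
  `+d_prevent`, `+d_CI`);
* **Wikidata-like** drug relations *subject has role*, *significant drug
  interaction*, *medical condition treated*, resolved by ATC / UMLS /
  RxNorm identifiers (`+wa`, `+wi`, `+wm`);
* **DBpedia-like** subjects of entities annotated in the free text,
  filtered to the medical domain by two constraints: the subject category
  must chain via `skos:broader` into a seed set of medical root categories,
  and the entity must be `owl:sameAs`-equivalent to a node typed with an
  allowed medical class (`+s`, `+s*`, `+s*T`, …, `+sm`).

Because cross-domain graphs also contribute noise, the `+s*m`/`+sm`
variants select concepts with an **L1-penalized logistic model run inside
the inner loop of a nested cross-validation**: word features always stay,
and a concept survives only if it adds signal beyond the text.  Concepts
selected in *every* outer fold form `+sm∩`; concepts selected in *at least
one* fold form `+sm∪`.

Evaluation uses a stratified K×L nested cross-validation with random
hyperparameter search (logistic regression, random forests, SVC), the
pooled F-score

> F<sub>tp,fp</sub> = 2·TP<sub>f</sub> / (2·TP<sub>f</sub> + FP<sub>f</sub> + FN<sub>f</sub>),

with confusion counts summed over folds, and the variance-corrected
dependent t-test
t = x̄ / √((1/n + n₂/n₁)·σ̂²) for per-fold metric differences, which
accounts for overlapping training sets.  Inter-annotator agreement of
concept relevance judgements is scored with nominal Krippendorff's α and
the centered-cosine correlation distance.

Since real primary-care cohorts are private, the package ships a
**synthetic-cohort generator**: hospitalization labels follow a logistic
model over planted *signal* concepts whose synonym surface forms (and
abbreviations) are injected into the free text, so the ability of the
pipeline to re-discover exactly those concepts — and the false-positive
rate on planted *noise* concepts — is measurable by construction.

## Worked example

```bash
python examples/04_evaluate_enrichment.py
```

prints (300-patient cohort, five planted concepts with log-odds weight 2):

```
baseline  pooled F = 0.6645, mean fold F1 = 0.6557
+sm       pooled F = 0.7591, mean fold F1 = 0.7540
corrected dependent t-test on F1: t = 3.02, p = 0.0145
```

The bag-of-words baseline fragments each planted concept over its synonym
and abbreviation columns; the enriched variant aggregates them into one
concept feature each, lifting the pooled F-score by ~0.09 — a difference
the corrected t-test judges significant at the 5% level.  The other
examples show cohort generation, the extraction worked examples (the
`C01DA38 → C01DA → C01D → C01` drug chain, the atorvastatin–pregnancy
contraindication, French free-text annotation with abbreviation
expansion), per-fold concept selection, and the agreement/risk formulas.

A complete multi-variant run from one YAML config:

```bash
kgemr run --config config.yaml --seed 1
```

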