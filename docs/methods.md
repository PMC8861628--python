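# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `kgemr`.

## Record aggregation and the label rule

A patient record consists of static free-text fields (personal history,
family history, past problems, allergies, environmental factors, current
problems) and an ordered list of consultations, each with seven free-text
fields (reasons, observations, symptoms, diagnoses, drugs, care
procedures, prescription reasons) plus ATC drug codes and ICPC-2 problem
codes.  The prediction target is binary: hospitalized vs not.

For hospitalized patients only the consultations strictly before the
hospitalization index contribute to the representation (static fields
always contribute); non-hospitalized patients contribute everything.  A
hospitalized record whose index is 0 carries no pre-hospitalization
evidence and is excluded from the design matrix with a warning.

## Vector representation

* **Bag of words.** Tokens are Unicode word characters after NFC
  normalization and casefolding, length ≥ 2, digits kept, hyphenated
  compounds split, accents preserved.  Each token is prefixed with a short
  field code (`obs:`, `fh:`, …) so the same word in different fields yields
  distinct features.  Values are raw counts; no tf-idf, no binarization.
* **Bag of concepts.** One column per distinct (source, property, concept)
  triple, named `SOURCE[:property]=label` (e.g.
  `NDFRT:CI_with=Pregnancy`); values are occurrence counts.
* The patient vector is the concatenation of the two blocks with a
  recorded boundary index.  Word and concept namespaces are disjoint by
  construction and concatenation errors on any collision.
* Every variant uses the full 13-field scope for the *word* block, so the
  V-block is identical across variants and any performance difference is
  attributable to the concept block.  The variant's field scope governs
  only concept extraction from free text (the `s*` family excludes family
  history, past problems and symptoms — fields describing relatives or
  resolved episodes rather than the patient's current record).

## Concept extraction

* **Hierarchy closures** walk a single relation (e.g. `rdfs:subClassOf`,
  `skos:broader`) breadth-first with a visited set (live category graphs
  contain cycles) and a default depth cap of 10.  ATC ancestor levels are
  numbered parent-first: level 1 is the direct super class, level 2 its
  parent.  ICPC-2 is flat, so at most one super class is extracted per
  code; two asserted parents are treated as a data error.
* **Drug relations.** NDF-RT drugs are matched through the UMLS CUI
  annotation carried by the ATC code.  Wikidata-like drugs are resolved by
  trying the ATC code property, then the UMLS CUI, then the RxNorm CUI.
  Relations are keyed by *label* (role / interaction / condition) because
  the upstream numeric property IDs are inconsistently reported; the IRIs
  behind the labels are configurable.
* **Free-text annotation** is a pluggable contract; the default dictionary
  annotator lowercases and NFC-normalizes the text, expands abbreviation
  tokens from the fixture dictionary, then takes longest non-overlapping
  matches against the surface-form dictionary.  A statistical annotator
  (e.g. a Spotlight client) can be plugged in without touching the rest of
  the pipeline.
* **Medical-domain filter.** An annotated entity contributes its subject
  categories only if (1) the subject's broader-closure (subject included)
  intersects the seed medical categories and (2) the entity is
  `owl:sameAs`-linked to at least one node carrying an allowed type.  The
  second constraint can only shrink the first's result set, a property the
  tests fuzz.

## Concept selection

Selection fits an L1-penalized logistic regression on the **full** training
matrix — word columns act as covariates, so a concept is only retained if
it explains labels beyond the text — and reads the selection off the
concept columns alone; word features are never removed.  Columns are
scaled to unit variance without centering (centering would densify the
sparse matrix).  The penalty grid is 20 log-spaced strengths in
[10⁻³, 10²], scored by mean F1 over the inner stratified folds.  The
chosen strength follows the **one-standard-error parsimony rule**: the
strongest penalty whose score is within one standard error of the best.
CV-optimal L1 penalties systematically over-select in noisy designs; the
1-SE rule (standard in the glmnet tradition) keeps the false-positive rate
on pure-noise concepts low (empirically ≲ 3 of 50 noise columns at
realistic training sizes) without hurting recovery of truly predictive
concepts.  Coefficients with |β| > 10⁻⁸ count as selected.

Per-fold selections induce two derived feature sets: the intersection
(concepts selected in all K outer folds) and the union (selected in at
least one).  The per-fold indicator vectors double as "machine annotators"
M₁..M_K with their union row U₁, comparable to human annotators through
Krippendorff's α and the correlation distance.

Note one quirk inherited from the upstream notation: for the
*human*-annotated subsets the `∩` variant keeps concepts judged relevant
by *at least one* annotator and `∪` those judged relevant by *all* — the
reverse of the set-theoretic reading — while the machine variants `+sm∩` /
`+sm∪` use the natural reading.  The registry follows the notation as
published.

## Evaluation

* Stratified outer K-fold (default 10) and inner L-fold splits (labels are
  binary, so stratification is the safe default).  Hyperparameters are
  drawn by random search — logistic regression (C ~ Exp(1), penalty l1/l2),
  SVC (C, gamma ~ Exp(1); linear/RBF/poly kernels), random forests (trees
  10–500, depth 5–30, split 2–30, leaf 1–5, leaf nodes 10–50) — scored by
  mean inner-fold F1 with first-best tie-breaking.  Scikit-learn requires
  `min_samples_split ≥ 2`, so the lower bound of that range is 2.
* The pooled score F_tp,fp sums confusion counts over outer folds before
  forming the F-measure and reduces to the ordinary F1 for a single fold.
  Per-fold precision/recall/F1/AUC are also averaged with sample standard
  deviations (ddof = 1).  AUC uses the decision function for margin
  classifiers and the positive-class probability otherwise.
* Variant comparisons use the variance-corrected dependent t-test on
  per-fold differences, t = x̄ / √((1/n + n₂/n₁)·σ̂²) with n−1 degrees of
  freedom and two-sided p-values; with K = 10, n₂/n₁ = 1/9.  The statistic
  is undefined at zero difference variance; identical variants are
  reported as identical rather than tested.  The correction is
  deliberately conservative: in the package's own null replication study
  (200 zero-effect cohorts) the empirical rejection rate at the 5% level
  is 1–3%.
* Krippendorff's α is implemented in the nominal coincidence-matrix form;
  units with fewer than two non-missing labels are dropped, and a
  single-category matrix returns α = 1 (trivial agreement).  The
  correlation distance is 1 − centered cosine, in [0, 2], and errors on
  constant vectors.
* Two display formulas summarize a risk prediction: the absolute reduction
  in percentage points (61% → 44% gives 17 points) and the relative gain
  rounded to whole percent (round(100·17/61) = 28%).

## Synthetic data-generating process

The generator emulates a balanced designed case–control cohort (defaults
714 hospitalized / 732 not, mirroring the reference study size) rather
than natural prevalence:

1. A knowledge fixture is generated with `n_signal` + `n_noise`
   DBpedia-like concepts — each one category reachable through one entity
   with `n_synonyms` synonym surface forms plus generated abbreviations —
   and random ATC chains (with CUIs), NDF-RT and Wikidata-like drug nodes,
   and ICPC-2 codes.  Hand-written reference content (the tenitramine ATC
   chain, the atorvastatin–pregnancy contraindication, the French
   heart-failure and cyst entities) is always included unless switched
   off.
2. Per candidate patient, each signal/noise concept is "exposed" with
   probability 0.3; the label is Bernoulli with logit = intercept + Σ
   planted weights over exposed signal concepts, the intercept centering
   the mean logit at zero.  Default weights are 2.0 log-odds per signal
   concept.  Exposed concepts inject 1–3 occurrences of a random synonym
   (abbreviated with probability 0.2) into random text slots among the
   usable consultations (pre-hospitalization only, for cases) and static
   fields; filler text is drawn from a `w0…wN` vocabulary (default 300
   words, 3–8 tokens per field, 3–8 consultations per patient).  Random
   ATC/ICPC-2 codes (0–2 per consultation) exercise the structured-code
   extraction routes but carry no label signal.
3. Rejection sampling continues until both class counts are exactly met,
   mimicking a designed balanced dataset.

The key realism feature is **synonym fragmentation**: a bag-of-words model
sees each planted concept split over several sparse synonym/abbreviation
columns, while concept extraction aggregates them into a single feature —
which is precisely the mechanism by which knowledge-graph enrichment can
beat the text baseline.  What the generator does *not* emulate: realistic
French clinical language (filler tokens are abstract), spelling errors,
negation and context, field-specific vocabularies, temporal visit
dynamics, or correlated comorbidity structure.  Passing tests therefore
demonstrate the machinery's correctness and its statistical behaviour
under a controlled signal model, not clinical performance on real records.

Text distributional parameters (field lengths, vocabulary size) have no
published reference values; the defaults above are stand-ins chosen for
plausible sparsity, and are explicit `CohortConfig` fields.

## Canned experiments and problem sizes

`kgemr.experiments` fixes two study designs used by the tests and the
acceptance script:

* **Recovery experiment** — reference-size cohort (1446 patients), 5
  signal concepts at weight 2.0, 30 noise concepts; K = 10, L = 3 with 3
  random-search iterations for logistic regression (the search space is
  small for this estimator, so a short search keeps the run at ~1 minute
  while leaving hyperparameter choice genuinely data-driven).  Measured
  outcomes: per-concept recovery across outer folds, union/intersection
  sizes, pooled F for baseline and enriched, corrected t and p.
* **Type-I error experiment** — 200 cohorts of 100 patients with *zero*
  signal concepts and 15 noise concepts, reduced text sizes, K = 10,
  L = 2, one search iteration; the rejection rate of the
  enriched-vs-baseline corrected t-test at the 5% level is the measured
  type-I error of the full comparison pipeline.  Zero-variance fold
  differences count as non-rejections.

## Determinism

Every stochastic component takes an explicit seed; pipeline runs derive
per-stage seeds (< 2³¹) from one master seed via `SeedSequence`, and
regenerating with the same configuration is byte-identical at the
serialization level (TSV cohort files, Turtle graphs, JSON reports).  The
run manifest records seeds and SHA-256 hashes of all artifacts.

## Known limitations

* The live-endpoint interface is limited to the pluggable annotator and
  configurable relation IRIs; no SPARQL-over-HTTP client is bundled, and
  federated queries would need to be decomposed by the caller.
* The selection step fits one L1 model per outer fold; stability selection
  or bootstrap variants are out of scope.
* Sequential (per-visit) modelling of records is deliberately not
  implemented; the representation is the aggregated non-sequential one.
* Absolute scores on any real cohort are out of reach by design — the
  synthetic generator controls the signal, so only relative and
  statistical claims (recovery, type-I error, significance of enrichment)
  are meaningful.
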