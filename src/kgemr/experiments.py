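"""Canned simulation experiments on fully synthetic cohorts.

Two study designs are provided:

* :func:`recovery_experiment` — a balanced cohort at the reference size
  (714 hospitalized / 732 not) with planted concept effects; measures how
  reliably L1 selection inside nested CV recovers the planted concepts and
  whether the enriched representation beats the bag-of-words baseline on
  per-fold F1 under the corrected dependent t-test.

* :func:`type_one_error_experiment` — many small cohorts with *zero*
  planted effect; measures how often the enriched-vs-baseline corrected
  t-test rejects at the 5% level, i.e. the type-I error of the full
  comparison pipeline.  Cohort and protocol sizes are scaled down so that
  hundreds of replicates stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortConfig, generate_cohort
from .evaluate import CVProtocol, nested_cv
from .fixtures import FixtureSpec, generate_kg_fixture
from .metrics import corrected_ttest
from .pipeline import derive_seeds
from .select import fold_intersection, fold_union

__all__ = ["RecoveryResult", "recovery_experiment",
           "type_one_error_experiment"]


@dataclass
class RecoveryResult:
    n_patients: int
    baseline_pooled_f: float
    enriched_pooled_f: float
    t_value: float
    p_value: float
    recovery_per_concept: list[int]  # folds (of K) selecting each concept
    n_folds: int
    union_size: int
    intersection_size: int
    baseline_f1_folds: list[float]
    enriched_f1_folds: list[float]


def recovery_experiment(seed: int = 0,
                        n_hospitalized: int = 714,
                        n_not_hospitalized: int = 732,
                        effect_size: float = 2.0,
                        n_signal_concepts: int = 5,
                        n_noise_concepts: int = 30,
                        K: int = 10, L: int = 3, n_iter: int = 3
                        ) -> RecoveryResult:
    """Planted-effect experiment: enriched (+sm with per-fold lasso
    selection) versus bag-of-words baseline, logistic regression."""
    fixture_seed, cohort_seed, eval_seed = derive_seeds(seed, 3)
    fixture = generate_kg_fixture(FixtureSpec(
        n_signal_concepts=n_signal_concepts,
        n_noise_concepts=n_noise_concepts, seed=fixture_seed))
    config = CohortConfig(
        n_hospitalized=n_hospitalized,
        n_not_hospitalized=n_not_hospitalized,
        n_signal_concepts=n_signal_concepts,
        n_noise_concepts=n_noise_concepts,
        effect_sizes=tuple([effect_size] * n_signal_concepts),
        seed=cohort_seed)
    cohort, truth = generate_cohort(config, fixture)

    from .vectorize import assemble_design_matrix
    baseline_matrix, y = assemble_design_matrix(cohort, fixture, "baseline")
    enriched_matrix, _ = assemble_design_matrix(cohort, fixture, "+sm")

    protocol = CVProtocol(K=K, L=L, n_iter=n_iter, seed=eval_seed)
    enriched = nested_cv(enriched_matrix, y, protocol,
                         selection_mode="lasso")
    baseline = nested_cv(baseline_matrix, y, protocol)

    planted = [f"DBPEDIA={c.label}"
               for c in fixture.signal_concepts[:n_signal_concepts]]
    selections = enriched.selections
    recovery = [sum(1 for s in selections if name in s.selected_concepts)
                for name in planted]
    t, p = corrected_ttest(enriched.per_fold("f1"),
                           baseline.per_fold("f1"),
                           n_train=K - 1, n_test=1)
    return RecoveryResult(
        n_patients=len(cohort),
        baseline_pooled_f=baseline.pooled_f,
        enriched_pooled_f=enriched.pooled_f,
        t_value=t, p_value=p,
        recovery_per_concept=recovery,
        n_folds=K,
        union_size=len(fold_union(selections)),
        intersection_size=len(fold_intersection(selections)),
        baseline_f1_folds=baseline.per_fold("f1"),
        enriched_f1_folds=enriched.per_fold("f1"))


def type_one_error_experiment(n_cohorts: int = 200, seed: int = 0,
                              n_per_class: int = 50,
                              n_noise_concepts: int = 15,
                              alpha: float = 0.05) -> dict:
    """Null-hypothesis replication study of the variant comparison.

    Every cohort has zero planted effect (no signal concepts); the enriched
    representation only adds label-irrelevant concept columns, so any
    rejection of enriched-vs-baseline is a false positive.  Returns the
    rejection rate over *n_cohorts* replicates; zero-variance fold
    differences (identical predictions) count as non-rejections.
    """
    from .vectorize import assemble_design_matrix

    rng_seeds = derive_seeds(seed, 3 * n_cohorts)
    rejections = 0
    degenerate = 0
    for i in range(n_cohorts):
        fseed, cseed, eseed = rng_seeds[3 * i:3 * i + 3]
        fixture = generate_kg_fixture(FixtureSpec(
            n_signal_concepts=0, n_noise_concepts=n_noise_concepts,
            n_synonyms=2, n_drugs=1, n_icpc2_codes=1,
            include_worked_examples=False, seed=fseed))
        config = CohortConfig(
            n_hospitalized=n_per_class, n_not_hospitalized=n_per_class,
            n_signal_concepts=0, n_noise_concepts=n_noise_concepts,
            vocab_size_words=60, consultations_per_patient=(2, 4),
            tokens_per_field=(2, 4), seed=cseed)
        cohort, _ = generate_cohort(config, fixture)
        baseline_matrix, y = assemble_design_matrix(cohort, fixture,
                                                    "baseline")
        enriched_matrix, _ = assemble_design_matrix(cohort, fixture, "+s*T")
        protocol = CVProtocol(K=10, L=2, n_iter=1, seed=eseed)
        baseline = nested_cv(baseline_matrix, y, protocol)
        enriched = nested_cv(enriched_matrix, y, protocol)
        try:
            _, p = corrected_ttest(enriched.per_fold("f1"),
                                   baseline.per_fold("f1"),
                                   n_train=9, n_test=1)
        except ZeroDivisionError:
            degenerate += 1
            continue
        if p < alpha:
            rejections += 1
    return {"n_cohorts": n_cohorts,
            "rejections": rejections,
            "degenerate": degenerate,
            "rejection_rate": rejections / n_cohorts,
            "nominal_level": alpha}
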