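"""Vectorization: tokenizer, prefixes, concatenation, aggregation rule and
the variant registry."""

from collections import Counter

import numpy as np
import pytest

from kgemr import (DesignMatrix, assemble_design_matrix, build_boc,
                   build_bow, concat, feature_set_spec, tokenize,
                   variant_names)
from kgemr.cohort import Consultation, PatientRecord
from kgemr.extract import ConceptAtom, ExtractionResult
from kgemr.fields import FULL_SCOPE, S_STAR_SCOPE


def _record(static=None, consultations=None, hospitalized=False,
            hosp_index=None):
    return PatientRecord(patient_id="P0", static_texts=static or {},
                         consultations=consultations or [],
                         hospitalized=hospitalized,
                         hospitalization_index=hosp_index)


# --- tokenizer and BOW ----------------------------------------------------

def test_tokenizer_rules():
    assert tokenize("Prédom à gche, b12-dosage") == \
        ["prédom", "gche", "b12", "dosage"]
    assert tokenize("a b c") == []  # single-char tokens dropped


def test_empty_record_zero_vector():
    assert build_bow(_record()) == Counter()


def test_tokens_are_field_prefixed():
    cons = [Consultation(order_index=0,
                         field_texts={"observations": "pas de phlébite"})]
    bow = build_bow(_record(consultations=cons))
    assert bow == Counter({"obs:pas": 1, "obs:de": 1, "obs:phlébite": 1})
    assert "phlébite" not in bow


def test_same_word_in_two_fields_two_features():
    rec = _record(static={"personal_history": "diabète",
                          "family_history": "diabète"})
    bow = build_bow(rec)
    assert bow == Counter({"ph:diabète": 1, "fh:diabète": 1})


def test_unknown_scope_field_is_an_error():
    with pytest.raises(ValueError):
        build_bow(_record(), field_scope=("bogus",))


def test_bow_aggregation_stops_at_hospitalization():
    cons = [
        Consultation(order_index=0, field_texts={"reasons": "alpha"}),
        Consultation(order_index=1, field_texts={"reasons": "beta"}),
        Consultation(order_index=2, field_texts={"reasons": "gamma"}),
    ]
    rec = _record(consultations=cons, hospitalized=True, hosp_index=2)
    bow = build_bow(rec)
    assert "rc:alpha" in bow and "rc:beta" in bow
    assert "rc:gamma" not in bow


# --- BOC and concatenation ------------------------------------------------

def test_boc_counts_property_concept_pairs():
    atom = ConceptAtom(source="NDFRT", concept="iri", label="Pregnancy",
                       property="CI_with")
    boc = build_boc(ExtractionResult("P0", Counter({atom: 2})))
    assert boc == Counter({"NDFRT:CI_with=Pregnancy": 2})


def test_boc_two_concepts_each_once():
    a1 = ConceptAtom(source="DBPEDIA", concept="i1", label="Organ failure")
    a2 = ConceptAtom(source="DBPEDIA", concept="i2",
                     label="Medical emergencies")
    boc = build_boc(ExtractionResult("P0", Counter({a1: 1, a2: 1})))
    assert boc == Counter({"DBPEDIA=Organ failure": 1,
                           "DBPEDIA=Medical emergencies": 1})


def test_concat_identity_under_empty_enrichment():
    V = Counter({"obs:a": 2, "rc:b": 1})
    assert concat(V, Counter()) == V


def test_concat_width_additivity_and_value_preservation():
    rng = np.random.default_rng(0)
    V = Counter({f"obs:w{i}": int(rng.integers(1, 9)) for i in range(5)})
    C = Counter({f"DBPEDIA=c{i}": int(rng.integers(1, 9)) for i in range(3)})
    x = concat(V, C)
    assert len(x) == 8
    assert sorted(x.values()) == sorted(list(V.values()) + list(C.values()))


def test_concat_namespace_collision_raises():
    with pytest.raises(ValueError):
        concat(Counter({"a": 1}), Counter({"a": 1}))


# --- variant registry -----------------------------------------------------

def test_registry_has_all_twenty_variants():
    assert len(variant_names()) == 20


def test_s_star_t_spec():
    spec = feature_set_spec("+s*T")
    assert spec.sources == {"DBPEDIA"}
    assert spec.selection_mode == "none"
    assert spec.field_scope == S_STAR_SCOPE
    for f in ("family_history", "past_problems", "symptoms"):
        assert f not in spec.field_scope


def test_sm_spec_full_scope_lasso():
    spec = feature_set_spec("+sm")
    assert spec.sources == {"DBPEDIA"}
    assert spec.selection_mode == "lasso"
    assert spec.field_scope == FULL_SCOPE


def test_baseline_spec_no_sources():
    assert feature_set_spec("baseline").sources == frozenset()


def test_ascii_aliases_resolve():
    assert feature_set_spec("+c1-2") is feature_set_spec("+c1−2")
    assert feature_set_spec("+sm_union") is feature_set_spec("+sm∪")


def test_unknown_variant_raises():
    with pytest.raises(KeyError):
        feature_set_spec("+zz")


def test_annotation_whitelist_any_vs_all():
    from kgemr import annotation_whitelist, simulate_annotators
    from kgemr.cohort import AnnotationMatrix

    cells = np.array([
        ["relevant", "relevant", "irrelevant"],
        ["relevant", "irrelevant", "irrelevant"],
    ], dtype=object)
    m = AnnotationMatrix(annotators=["A_1", "A_2"],
                         universe=["c0", "c1", "c2"], cells=cells)
    assert annotation_whitelist(m, "any") == {"c0", "c1"}
    assert annotation_whitelist(m, "all") == {"c0"}
    with pytest.raises(ValueError):
        annotation_whitelist(m, "some")


def test_annotation_variant_requires_whitelist(fixture, small_cohort):
    from kgemr import ConfigurationError
    records, _ = small_cohort
    with pytest.raises(ConfigurationError):
        assemble_design_matrix(records, fixture, "+s*∩")
    spec = feature_set_spec("+s*∩").with_whitelist({"sig category 0"})
    matrix, _ = assemble_design_matrix(records[:5], fixture, spec)
    assert set(matrix.concept_columns) <= {"DBPEDIA=sig category 0"}


# --- design matrix assembly ----------------------------------------------

def test_baseline_matrix_has_empty_concept_block(fixture, small_cohort):
    records, _ = small_cohort
    matrix, y = assemble_design_matrix(records, fixture, "baseline")
    assert matrix.boundary == matrix.X.shape[1]
    assert matrix.concept_columns == []
    assert len(y) == len(records)


def test_vblock_identical_across_variants(fixture, small_cohort):
    records, _ = small_cohort
    mb, _ = assemble_design_matrix(records, fixture, "baseline")
    ms, _ = assemble_design_matrix(records, fixture, "+sm")
    assert mb.col_names == ms.word_columns
    assert (mb.X != ms.X[:, :ms.boundary]).nnz == 0


def test_column_sums_conserve_token_counts(fixture, small_cohort):
    records, _ = small_cohort
    matrix, _ = assemble_design_matrix(records, fixture, "baseline")
    total_tokens = sum(sum(build_bow(r).values()) for r in records)
    assert matrix.X.sum() == total_tokens


def test_assembly_permutation_invariant(fixture, small_cohort):
    records, _ = small_cohort
    m1, y1 = assemble_design_matrix(records, fixture, "+t")
    rev = list(reversed(records))
    m2, y2 = assemble_design_matrix(rev, fixture, "+t")
    assert m1.col_names == m2.col_names
    order = [m2.row_ids.index(r) for r in m1.row_ids]
    assert (m1.X != m2.X[order]).nnz == 0
    assert (y1 == y2[order]).all()


def test_hospitalization_at_index_zero_is_excluded(fixture):
    rec = PatientRecord(
        patient_id="PX", static_texts={"allergies": "pollen"},
        consultations=[Consultation(order_index=0,
                                    field_texts={"reasons": "x"})],
        hospitalized=True, hospitalization_index=0)
    matrix, y = assemble_design_matrix([rec], fixture, "baseline")
    assert matrix.row_ids == []
    assert len(y) == 0


def test_matrix_roundtrip(fixture, small_cohort, tmp_path):
    records, _ = small_cohort
    matrix, _ = assemble_design_matrix(records[:10], fixture, "+sm")
    matrix.save(tmp_path)
    loaded = DesignMatrix.load(tmp_path)
    assert loaded.col_names == matrix.col_names
    assert loaded.row_ids == matrix.row_ids
    assert loaded.boundary == matrix.boundary
    assert (loaded.X != matrix.X).nnz == 0
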