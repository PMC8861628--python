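"""Concept extraction: worked examples, brute-force oracle agreement and
structural properties."""

import numpy as np
import pytest
from rdflib import RDFS, SKOS, Graph, Literal, Namespace, URIRef

from kgemr import (ConceptAtom, annotate_text, atc_ancestors,
                   broader_closure, dbpedia_candidate_subjects, extract_all,
                   icpc2_ancestor, ndfrt_pairs, wikidata_pairs)
from kgemr.cohort import Consultation, PatientRecord
from kgemr.fixtures import (ATC, ICPC, CUI_PROP, FixtureSpec, NDFRT,
                            NDFRT_PROPERTIES, WDT_ATC, WDT_CUI, WDT_RXNORM,
                            WIKIDATA_RELATIONS, generate_kg_fixture)
from kgemr.vectorize import feature_set_spec

from .oracles import bfs_ancestors, edge_map, scan_pairs, \
    two_pass_medical_filter

EX = Namespace("http://example.org/test/")


# --- broader_closure ------------------------------------------------------

def test_closure_of_leafless_node_is_empty():
    g = Graph()
    g.add((EX.a, SKOS.prefLabel, Literal("a")))
    assert broader_closure(EX.a, g, SKOS.broader) == set()


def test_atc_worked_chain_closure(fixture):
    atc = fixture.graphs["ATC"]
    closure = broader_closure(ATC["C01DA38"], atc, RDFS.subClassOf,
                              max_depth=10)
    assert closure == {ATC["C01DA"], ATC["C01D"], ATC["C01"]}


def test_closure_equals_bfs_oracle_on_random_dags():
    rng = np.random.default_rng(42)
    for _ in range(20):
        g = Graph()
        nodes = [EX[f"n{i}"] for i in range(30)]
        # edges only towards higher indices: a DAG by construction
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.12:
                    g.add((nodes[i], SKOS.broader, nodes[j]))
        edges = edge_map(g, SKOS.broader)
        start = nodes[int(rng.integers(0, 10))]
        if (start, None, None) not in g and (None, None, start) not in g:
            continue
        for depth in (1, 3, 10):
            assert (broader_closure(start, g, SKOS.broader, depth)
                    == bfs_ancestors(edges, start, depth))


def test_closure_is_cycle_safe():
    g = Graph()
    g.add((EX.a, SKOS.broader, EX.b))
    g.add((EX.b, SKOS.broader, EX.a))
    assert broader_closure(EX.a, g, SKOS.broader, 10) == {EX.b}


def test_closure_monotone_under_triple_addition():
    rng = np.random.default_rng(7)
    g = Graph()
    nodes = [EX[f"m{i}"] for i in range(15)]
    g.add((nodes[0], SKOS.broader, nodes[1]))
    prev = broader_closure(nodes[0], g, SKOS.broader, 10)
    for _ in range(40):
        i, j = rng.integers(0, 15, size=2)
        if i == j:
            continue
        g.add((nodes[int(i)], SKOS.broader, nodes[int(j)]))
        cur = broader_closure(nodes[0], g, SKOS.broader, 10)
        assert cur >= prev
        prev = cur


# --- ATC / ICPC-2 ---------------------------------------------------------

def test_atc_ancestors_worked_levels(fixture):
    atc = fixture.graphs["ATC"]
    level1 = atc_ancestors("C01DA38", atc, levels={1})
    assert [a.concept for a in level1] == [str(ATC["C01DA"])]
    assert level1[0].depth == 1
    assert level1[0].label == "Organic nitrates used in cardiac disease"
    level2 = atc_ancestors("C01DA38", atc, levels={2})
    assert [a.concept for a in level2] == [str(ATC["C01D"])]
    both = atc_ancestors("C01DA38", atc, levels={1, 2})
    assert {a.concept for a in both} == {str(ATC["C01DA"]), str(ATC["C01D"])}


def test_atc_root_has_no_parent(fixture):
    assert atc_ancestors("C01", fixture.graphs["ATC"], levels={1}) == []


def test_atc_unknown_code_empty(fixture):
    assert atc_ancestors("Z99ZZ99", fixture.graphs["ATC"], levels={1}) == []


def test_icpc2_ancestor_fixture_lookup_oracle(fixture):
    icpc = fixture.graphs["ICPC2"]
    for code in fixture.icpc2_codes:
        atoms = icpc2_ancestor(code, icpc)
        node = icpc.value(predicate=SKOS.notation, object=Literal(code))
        expected = scan_pairs(icpc, node, RDFS.subClassOf)
        assert {URIRef(a.concept) for a in atoms} == expected
        assert len(atoms) <= 1


def test_icpc2_absent_code_empty(fixture):
    assert icpc2_ancestor("Q00", fixture.graphs["ICPC2"]) == []


def test_icpc2_two_parents_is_invariant_violation():
    g = Graph()
    node = ICPC["K77"]
    g.add((node, SKOS.notation, Literal("K77")))
    g.add((node, RDFS.subClassOf, ICPC["K"]))
    g.add((node, RDFS.subClassOf, ICPC["R"]))
    with pytest.raises(ValueError):
        icpc2_ancestor("K77", g)


# --- NDF-RT / Wikidata ----------------------------------------------------

def test_ndfrt_atorvastatin_contraindication(fixture):
    atoms = ndfrt_pairs("C10AA05", fixture.graphs["ATC"],
                        fixture.graphs["NDFRT"], properties=["CI_with"])
    assert [(a.source, a.property, a.label) for a in atoms] == [
        ("NDFRT", "CI_with", "Pregnancy")]


def test_ndfrt_drug_without_triples_empty(fixture):
    # tenitramine has no CUI in the fixture
    assert ndfrt_pairs("C01DA38", fixture.graphs["ATC"],
                       fixture.graphs["NDFRT"]) == []


def test_ndfrt_equals_triple_scan_oracle():
    fx = generate_kg_fixture(FixtureSpec(seed=13, n_drugs=12))
    atc, ndfrt = fx.graphs["ATC"], fx.graphs["NDFRT"]
    for code in fx.atc_leaf_codes:
        node = atc.value(predicate=SKOS.notation, object=Literal(code))
        cui = atc.value(node, CUI_PROP)
        atoms = ndfrt_pairs(code, atc, ndfrt)
        expected = set()
        if cui is not None:
            drugs = {s for s, p, o in ndfrt
                     if p == CUI_PROP and o == Literal(str(cui))}
            for drug in drugs:
                for name, prop in NDFRT_PROPERTIES.items():
                    for obj in scan_pairs(ndfrt, drug, prop):
                        expected.add((name, str(obj)))
        assert {(a.property, a.concept) for a in atoms} == expected


def test_wikidata_resolution_order_and_oracle():
    fx = generate_kg_fixture(FixtureSpec(seed=21, n_drugs=16))
    wd, atc = fx.graphs["WIKIDATA"], fx.graphs["ATC"]
    for code in fx.atc_leaf_codes:
        node = atc.value(predicate=SKOS.notation, object=Literal(code))
        cui = atc.value(node, CUI_PROP)
        ids = {"atc": code}
        if cui is not None:
            ids["cui"] = str(cui)
        atoms = wikidata_pairs(ids, wd)
        # oracle: resolve in the documented order, then scan triples
        wnode = None
        for prop, val in ((WDT_ATC, code), (WDT_CUI, ids.get("cui")),
                          (WDT_RXNORM, None)):
            if val is None:
                continue
            hits = {s for s, p, o in wd
                    if p == prop and o == Literal(val)}
            if hits:
                wnode = hits.pop()
                break
        expected = set()
        if wnode is not None:
            for name, prop in WIKIDATA_RELATIONS.items():
                for obj in scan_pairs(wd, wnode, prop):
                    expected.add((name, str(obj)))
        assert {(a.property, a.concept) for a in atoms} == expected


def test_wikidata_multi_identifier_resolution_is_idempotent(fixture):
    wd = fixture.graphs["WIKIDATA"]
    both = wikidata_pairs({"atc": "C10AA05", "cui": "C0286651"}, wd)
    only_atc = wikidata_pairs({"atc": "C10AA05"}, wd)
    only_rx = wikidata_pairs({"rxnorm": "83367"}, wd)
    key = lambda atoms: sorted((a.property, a.concept) for a in atoms)
    assert key(both) == key(only_atc) == key(only_rx)


def test_wikidata_unresolvable_identifiers_empty(fixture):
    assert wikidata_pairs({"atc": "Z99ZZ99"},
                          fixture.graphs["WIKIDATA"]) == []


def test_wikidata_no_identifiers_is_an_error(fixture):
    with pytest.raises(ValueError):
        wikidata_pairs({}, fixture.graphs["WIKIDATA"])


# --- annotation and the medical-domain filter -----------------------------

def test_empty_text_no_mentions(fixture):
    assert annotate_text("", fixture) == []


def test_kyste_mention_links_to_cyst_entity(fixture):
    mentions = annotate_text("kyste", fixture)
    assert len(mentions) == 1
    assert mentions[0].entity.endswith("Kyste_(m%C3%A9decine)") or \
        "Kyste" in str(mentions[0].entity)


def test_abbreviation_expansion_matches_heart_failure(fixture):
    mentions = annotate_text("insuf cardiaque persistante", fixture)
    assert [str(m.entity) for m in mentions] == [
        "http://example.org/dbpedia/resource/Insuffisance_cardiaque"]


def test_longest_match_is_preferred(fixture):
    # "insuffisance cardiaque" must win over any shorter match and the two
    # tokens must not produce overlapping mentions
    mentions = annotate_text("insuffisance cardiaque", fixture)
    assert len(mentions) == 1
    assert mentions[0].surface == "insuffisance cardiaque"


def test_heart_failure_subjects_worked_example(fixture):
    mentions = annotate_text("insuffisance cardiaque", fixture)
    atoms = dbpedia_candidate_subjects(mentions, fixture)
    assert sorted(a.label for a in atoms) == ["Cardiovascular disease",
                                              "Organ failure"]


def test_entity_outside_seed_hierarchy_is_excluded(fixture):
    from rdflib import OWL, RDF
    from rdflib.namespace import DCTERMS
    from kgemr.extract import EntityMention
    from kgemr.fixtures import DBC, DBO, DBR, DBR_EN

    g = fixture.graphs["DBPEDIA"]
    ent = DBR["Orphan_entity"]
    cat = DBC["Unrooted_category"]  # no broader chain to any seed
    g.add((ent, DCTERMS.subject, cat))
    en = DBR_EN["Orphan_en"]
    g.add((ent, OWL.sameAs, en))
    g.add((en, RDF.type, DBO["Disease"]))
    try:
        atoms = dbpedia_candidate_subjects(
            [EntityMention("orphan", ent, "obs", 0)], fixture)
        assert atoms == []
    finally:
        g.remove((ent, None, None))
        g.remove((en, None, None))


def test_constraint2_never_enlarges_constraint1(fixture):
    """Dropping the type constraint can only grow the result set."""
    from kgemr.extract import EntityMention
    from rdflib.namespace import DCTERMS

    g = fixture.graphs["DBPEDIA"]
    entities = sorted(set(g.subjects(DCTERMS.subject, None)))
    mentions = [EntityMention("x", e, "obs", 0) for e in entities]
    both = {(a.concept) for a in
            dbpedia_candidate_subjects(mentions, fixture)}
    only_c1 = set()
    from kgemr.extract import broader_closure as bc
    from rdflib import SKOS
    seeds = set(fixture.seed_categories)
    for e in entities:
        for subj in g.objects(e, DCTERMS.subject):
            if ({subj} | bc(subj, g, SKOS.broader, 10)) & seeds:
                only_c1.add(str(subj))
    assert both <= only_c1


def test_medical_filter_equals_two_pass_oracle_random_fixtures():
    from rdflib.namespace import DCTERMS
    from kgemr.extract import EntityMention

    for seed in range(10):
        fx = generate_kg_fixture(FixtureSpec(seed=seed, n_signal_concepts=8,
                                             n_noise_concepts=12))
        g = fx.graphs["DBPEDIA"]
        entities = sorted(set(g.subjects(DCTERMS.subject, None)))
        mentions = [EntityMention("x", e, "obs", 0) for e in entities]
        got = {(m.entity, URIRef(a.concept)) for m in mentions
               for a in dbpedia_candidate_subjects([m], fx)}
        expected = two_pass_medical_filter(g, entities,
                                           fx.seed_categories,
                                           fx.allowed_classes)
        assert got == expected


# --- extract_all ----------------------------------------------------------

def _record_with(atc=(), icpc=(), text=""):
    cons = [Consultation(order_index=0,
                         field_texts={"observations": text},
                         atc_codes=list(atc), icpc2_codes=list(icpc))]
    return PatientRecord(patient_id="P0", static_texts={},
                         consultations=cons, hospitalized=False)


def test_baseline_variant_extracts_nothing(fixture, small_cohort):
    records, _ = small_cohort
    result = extract_all(records[0], fixture, "baseline")
    assert result.atoms == {}


def test_d_ci_variant_counts_duplicate_prescriptions(fixture):
    record = _record_with(atc=["C10AA05", "C10AA05"])
    result = extract_all(record, fixture, "+d_CI")
    atoms = {(a.property, a.label): n for a, n in result.atoms.items()}
    assert atoms == {("CI_with", "Pregnancy"): 2}


def test_t_variant_ignores_free_text(fixture):
    record = _record_with(icpc=["K77"], text="insuffisance cardiaque kyste")
    result = extract_all(record, fixture, "+t")
    assert all(a.source == "ICPC2" for a in result.atoms)
    assert len(result.atoms) == 1


def test_extract_all_is_deterministic(fixture, small_cohort):
    records, _ = small_cohort
    r = records[0]
    a = extract_all(r, fixture, "+sm").atoms
    b = extract_all(r, fixture, "+sm").atoms
    assert a == b


def test_extract_all_unknown_variant_raises(fixture, small_cohort):
    records, _ = small_cohort
    with pytest.raises(KeyError):
        extract_all(records[0], fixture, "+nope")


def test_extract_all_respects_prehospitalization_rule(fixture):
    cons = [
        Consultation(order_index=0, field_texts={"observations": "kyste"}),
        Consultation(order_index=1,
                     field_texts={"observations": "insuffisance cardiaque"}),
    ]
    record = PatientRecord(patient_id="P1", static_texts={},
                           consultations=cons, hospitalized=True,
                           hospitalization_index=1)
    result = extract_all(record, fixture, "+sm")
    labels = {a.label for a in result.atoms}
    assert labels == {"Neoplasm stubs"}  # only the pre-hospitalization visit
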