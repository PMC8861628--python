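"""Concept extraction from knowledge graphs.

Turns a patient record into a multiset of provenance-tagged concept atoms:

* ATC codes are expanded into hierarchy ancestors at requested depth levels
  (level 1 = direct parent, level 2 = grandparent, ...);
* ICPC-2 codes yield at most one super class (the thesaurus is flat);
* NDF-RT drug relations (may_treat / may_prevent / CI_with) are reached from
  an ATC code through its UMLS CUI annotation;
* Wikidata-like drug relations are reached by resolving the drug node via
  ATC code, UMLS CUI or RxNorm CUI, in that order;
* free-text entity mentions are found by a dictionary annotator
  (longest-match after NFC + casefold normalization, with abbreviation
  expansion) and filtered to the medical domain by the two-constraint rule:
  the mention's subject category must chain by skos:broader into a seed
  medical category, and the entity must be owl:sameAs-equivalent to a node
  typed with an allowed medical class.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from rdflib import RDF, RDFS, SKOS, OWL, Graph, Literal, URIRef
from rdflib.namespace import DCTERMS

from .cohort import PatientRecord
from .fixtures import (ATC, ICPC, CUI_PROP, NDFRT_PROPERTIES,
                       WIKIDATA_RELATIONS, WDT_ATC, WDT_CUI, WDT_RXNORM,
                       ConfigurationError, KnowledgeFixture, normalize)

logger = logging.getLogger(__name__)

__all__ = [
    "ConceptAtom",
    "EntityMention",
    "ExtractionResult",
    "broader_closure",
    "atc_ancestors",
    "icpc2_ancestor",
    "ndfrt_pairs",
    "wikidata_pairs",
    "annotate_text",
    "dictionary_annotator",
    "dbpedia_candidate_subjects",
    "extract_all",
]


# the ConceptAtom field named ``property`` shadows the builtin in its class
# body, so keep an alias for the decorator
_builtin_property = property


@dataclass(frozen=True)
class ConceptAtom:
    """One bag-of-concepts feature unit.

    ``property`` is set only for relation sources (NDFRT, WIKIDATA);
    ``depth`` only for ATC hierarchy ancestors.
    """

    source: str
    concept: str  # IRI
    label: str
    property: Optional[str] = None
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.property is not None) != (self.source in ("NDFRT", "WIKIDATA")):
            raise ValueError("property present iff source is NDFRT/WIKIDATA")
        if (self.depth is not None) != (self.source == "ATC"):
            raise ValueError("depth present iff source is ATC")

    @_builtin_property
    def feature_name(self) -> str:
        if self.property is not None:
            return f"{self.source}:{self.property}={self.label}"
        return f"{self.source}={self.label}"


@dataclass(frozen=True)
class EntityMention:
    surface: str
    entity: URIRef
    field: str
    offset: int


@dataclass
class ExtractionResult:
    patient_id: str
    atoms: Counter  # ConceptAtom -> occurrence count


def _label(graph: Graph, node: URIRef) -> str:
    lab = graph.value(node, SKOS.prefLabel)
    return str(lab) if lab is not None else str(node)


# --- hierarchy walks ------------------------------------------------------

def broader_closure(start: URIRef, graph: Graph, relation: URIRef,
                    max_depth: int = 10) -> set[URIRef]:
    """Transitive ancestors of *start* via *relation*, up to *max_depth*
    hops, excluding *start* itself.  Cycle-safe; an absent start node yields
    an empty set with a warning."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if (start, None, None) not in graph and (None, None, start) not in graph:
        logger.warning("node %s absent from graph", start)
        return set()
    seen: set[URIRef] = set()
    frontier = {start}
    for _ in range(max_depth):
        nxt = set()
        for node in frontier:
            for parent in graph.objects(node, relation):
                if parent not in seen and parent != start:
                    seen.add(parent)
                    nxt.add(parent)
        if not nxt:
            break
        frontier = nxt
    return seen


def _atc_node(graph: Graph, code: str) -> URIRef | None:
    node = graph.value(predicate=SKOS.notation, object=Literal(code))
    if node is None and ATC[code] in set(graph.subjects()):
        node = ATC[code]
    return node


def atc_ancestors(code: str, graph: Graph,
                  levels: Iterable[int] = (1,)) -> list[ConceptAtom]:
    """Hierarchy ancestors of an ATC code at exactly the requested depth
    levels (1 = direct super class)."""
    levels = set(levels)
    if not levels or any(l < 1 for l in levels):
        raise ValueError("levels must be a non-empty set of integers >= 1")
    node = _atc_node(graph, code)
    if node is None:
        logger.warning("ATC code %s not in graph", code)
        return []
    atoms = []
    depth = 0
    current = node
    max_level = max(levels)
    while depth < max_level:
        parent = graph.value(current, RDFS.subClassOf)
        if parent is None:
            break
        depth += 1
        if depth in levels:
            atoms.append(ConceptAtom(source="ATC", concept=str(parent),
                                     label=_label(graph, parent), depth=depth))
        current = parent
    return atoms


def icpc2_ancestor(code: str, graph: Graph) -> list[ConceptAtom]:
    """At most one super class per ICPC-2 code; more than one asserted
    parent violates the thesaurus shape and raises."""
    node = graph.value(predicate=SKOS.notation, object=Literal(code))
    if node is None:
        logger.warning("ICPC-2 code %s not in graph", code)
        return []
    parents = list(graph.objects(node, RDFS.subClassOf))
    if len(parents) > 1:
        raise ValueError(f"ICPC-2 code {code} has {len(parents)} parents; "
                         "expected at most one")
    return [ConceptAtom(source="ICPC2", concept=str(p), label=_label(graph, p))
            for p in parents]


# --- drug relations -------------------------------------------------------

def _atc_cui(atc_graph: Graph, code: str) -> str | None:
    node = _atc_node(atc_graph, code)
    if node is None:
        return None
    cui = atc_graph.value(node, CUI_PROP)
    return str(cui) if cui is not None else None


def ndfrt_pairs(atc_code: str, atc_graph: Graph, ndfrt_graph: Graph,
                properties: Iterable[str] = ("may_treat", "may_prevent",
                                             "CI_with")) -> list[ConceptAtom]:
    """Property-concept pairs of the NDF-RT drug matched to *atc_code*
    through its UMLS CUI annotation."""
    props = list(properties)
    unknown = [p for p in props if p not in NDFRT_PROPERTIES]
    if unknown:
        raise ValueError(f"unknown NDF-RT properties: {unknown}")
    cui = _atc_cui(atc_graph, atc_code)
    if cui is None:
        logger.warning("no CUI for ATC code %s", atc_code)
        return []
    drug = ndfrt_graph.value(predicate=CUI_PROP, object=Literal(cui))
    if drug is None:
        return []
    atoms = []
    for p in props:
        for obj in ndfrt_graph.objects(drug, NDFRT_PROPERTIES[p]):
            atoms.append(ConceptAtom(source="NDFRT", concept=str(obj),
                                     label=_label(ndfrt_graph, obj),
                                     property=p))
    return atoms


def wikidata_pairs(identifiers: dict[str, str], wd_graph: Graph,
                   relations: Iterable[str] = ("role", "interaction",
                                               "condition")
                   ) -> list[ConceptAtom]:
    """Resolve a drug node by ATC code, then UMLS CUI, then RxNorm CUI, and
    return its property-concept pairs for the requested relations.

    *identifiers* maps any of 'atc', 'cui', 'rxnorm' to a code string.
    """
    rels = list(relations)
    unknown = [r for r in rels if r not in WIKIDATA_RELATIONS]
    if unknown:
        raise ValueError(f"unknown Wikidata relations: {unknown}")
    if not identifiers:
        raise ValueError("at least one identifier is required")
    node = None
    for key, prop in (("atc", WDT_ATC), ("cui", WDT_CUI),
                      ("rxnorm", WDT_RXNORM)):
        value = identifiers.get(key)
        if value is not None:
            node = wd_graph.value(predicate=prop, object=Literal(value))
            if node is not None:
                break
    if node is None:
        logger.warning("no Wikidata node resolves identifiers %s", identifiers)
        return []
    atoms = []
    for r in rels:
        for obj in wd_graph.objects(node, WIKIDATA_RELATIONS[r]):
            atoms.append(ConceptAtom(source="WIKIDATA", concept=str(obj),
                                     label=_label(wd_graph, obj), property=r))
    return atoms


# --- free-text annotation -------------------------------------------------

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)

Annotator = Callable[[str, KnowledgeFixture, str], list[EntityMention]]


def dictionary_annotator(text: str, fixture: KnowledgeFixture,
                         field: str = "") -> list[EntityMention]:
    """Longest-match, non-overlapping dictionary annotation.

    The text is NFC-normalized and casefolded; abbreviation tokens are
    expanded before matching, and multi-token surface forms are matched
    greedily from each token position.
    """
    if not text:
        return []
    norm = normalize(text)
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(norm)]
    expanded = [(fixture.abbreviations.get(tok, tok), start)
                for tok, start in tokens]
    max_len = max((len(s.split()) for s in fixture.surface_forms), default=1)

    mentions: list[EntityMention] = []
    i = 0
    while i < len(expanded):
        matched = False
        for width in range(min(max_len, len(expanded) - i), 0, -1):
            candidate = " ".join(tok for tok, _ in expanded[i:i + width])
            entity = fixture.surface_forms.get(candidate)
            if entity is not None:
                mentions.append(EntityMention(
                    surface=candidate, entity=entity, field=field,
                    offset=expanded[i][1]))
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def annotate_text(text: str, fixture: KnowledgeFixture, field: str = "",
                  annotator: Annotator | None = None) -> list[EntityMention]:
    """Annotate *text* with the pluggable annotator contract; the dictionary
    annotator is the default."""
    annotator = annotator or dictionary_annotator
    return annotator(text, fixture, field)


def dbpedia_candidate_subjects(mentions: list[EntityMention],
                               fixture: KnowledgeFixture,
                               seed_categories: Iterable[URIRef]
                               | None = None,
                               allowed_classes: Iterable[URIRef]
                               | None = None,
                               max_depth: int = 10) -> list[ConceptAtom]:
    """Subjects of mentioned entities passing both medical-domain
    constraints.

    Constraint 1: the subject category's broader-closure (category included)
    intersects the seed categories.  Constraint 2: the entity is sameAs-linked
    to at least one node typed with an allowed class.  One atom is returned
    per (mention, qualifying subject); counts accumulate in the caller.
    """
    graph = fixture.graphs["DBPEDIA"]
    seeds = set(seed_categories if seed_categories is not None
                else fixture.seed_categories)
    classes = set(allowed_classes if allowed_classes is not None
                  else fixture.allowed_classes)
    if not seeds or not classes:
        raise ConfigurationError("seed categories and allowed classes "
                                 "must be non-empty")

    atoms = []
    for mention in mentions:
        # constraint 2 on the entity
        typed_ok = False
        for twin in graph.objects(mention.entity, OWL.sameAs):
            if any((twin, RDF.type, k) in graph for k in classes):
                typed_ok = True
                break
        if not typed_ok:
            continue
        # constraint 1 on each subject
        for subject in graph.objects(mention.entity, DCTERMS.subject):
            closure = {subject} | broader_closure(subject, graph,
                                                  SKOS.broader, max_depth)
            if closure & seeds:
                atoms.append(ConceptAtom(source="DBPEDIA",
                                         concept=str(subject),
                                         label=_label(graph, subject)))
    return atoms


# --- per-record dispatch --------------------------------------------------

def extract_all(record: PatientRecord, fixture: KnowledgeFixture,
                variant) -> ExtractionResult:
    """Run the extraction operations a feature-set variant requests and
    accumulate atom occurrence counts.

    *variant* is a :class:`kgemr.vectorize.FeatureSetSpec` (or a registered
    variant name).  Only pre-hospitalization consultations (plus static
    texts) contribute, matching the aggregation rule of the design matrix.
    """
    from .vectorize import FeatureSetSpec, feature_set_spec

    if isinstance(variant, str):
        variant = feature_set_spec(variant)
    if not isinstance(variant, FeatureSetSpec):
        raise TypeError("variant must be a FeatureSetSpec or variant name")

    atoms: Counter = Counter()
    consultations = record.contributing_consultations()
    atc_graph = fixture.graphs["ATC"]

    if "ATC" in variant.sources:
        for c in consultations:
            for code in c.atc_codes:
                for atom in atc_ancestors(code, atc_graph,
                                          levels=variant.atc_levels):
                    atoms[atom] += 1
    if "ICPC2" in variant.sources:
        for c in consultations:
            for code in c.icpc2_codes:
                for atom in icpc2_ancestor(code, fixture.graphs["ICPC2"]):
                    atoms[atom] += 1
    if "NDFRT" in variant.sources:
        for c in consultations:
            for code in c.atc_codes:
                for atom in ndfrt_pairs(code, atc_graph,
                                        fixture.graphs["NDFRT"],
                                        properties=variant.ndfrt_properties):
                    atoms[atom] += 1
    if "WIKIDATA" in variant.sources:
        for c in consultations:
            for code in c.atc_codes:
                identifiers = {"atc": code}
                cui = _atc_cui(atc_graph, code)
                if cui is not None:
                    identifiers["cui"] = cui
                for atom in wikidata_pairs(identifiers,
                                           fixture.graphs["WIKIDATA"],
                                           relations=variant.wikidata_relations):
                    atoms[atom] += 1
    if "DBPEDIA" in variant.sources:
        texts: list[tuple[str, str]] = []
        for f in variant.field_scope:
            if f in record.static_texts:
                texts.append((f, record.static_texts[f]))
        for c in consultations:
            for f in variant.field_scope:
                if f in c.field_texts:
                    texts.append((f, c.field_texts[f]))
        for f, text in texts:
            mentions = annotate_text(text, fixture, field=f,
                                     annotator=variant.annotator)
            for atom in dbpedia_candidate_subjects(mentions, fixture):
                atoms[atom] += 1

    if variant.concept_whitelist is not None:
        atoms = Counter({a: n for a, n in atoms.items()
                         if a.label in variant.concept_whitelist})
    return ExtractionResult(patient_id=record.patient_id, atoms=atoms)
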