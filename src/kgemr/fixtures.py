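"""Synthetic knowledge-graph fixtures.

Miniature RDF stand-ins for the five knowledge sources the extraction stage
queries: the ATC drug hierarchy, the ICPC-2 primary-care thesaurus, NDF-RT
drug relations, a Wikidata-like drug graph and a DBpedia-like
category/type graph, together with a surface-form dictionary used for
entity annotation of free text.

The generated fixture always contains a handful of hand-written entries
that mirror well-known reference content (the tenitramine ATC chain
C01DA38 -> C01DA -> C01D -> C01, the atorvastatin contraindication with
pregnancy, the French "insuffisance cardiaque" and "kyste" entities), plus
a seeded random population of drugs, codes and medical concepts.  Concepts
are split into *signal* concepts, to which the cohort generator can attach
label effects, and *noise* concepts that behave identically in every graph
but carry no effect.
"""

from __future__ import annotations

import json
import string
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdflib import RDF, RDFS, SKOS, OWL, Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS

__all__ = [
    "ConfigurationError",
    "FixtureSpec",
    "ConceptInfo",
    "KnowledgeFixture",
    "generate_kg_fixture",
    "normalize",
]

# --- namespaces -----------------------------------------------------------

ATC = Namespace("http://example.org/atc/")
ICPC = Namespace("http://example.org/icpc2/")
NDFRT = Namespace("http://example.org/ndfrt/")
WD = Namespace("http://example.org/wd/entity/")
WDT = Namespace("http://example.org/wd/prop/")
DBR = Namespace("http://example.org/dbpedia/resource/")
DBC = Namespace("http://example.org/dbpedia/category/")
DBR_EN = Namespace("http://example.org/dbpedia-en/resource/")
DBO = Namespace("http://dbpedia.org/ontology/")
YAGO = Namespace("http://dbpedia.org/class/yago/")
UMLS = Namespace("http://bioportal.bioontology.org/ontologies/umls/")

CUI_PROP = UMLS["cui"]

# NDF-RT drug relations.
MAY_TREAT = NDFRT["may_treat"]
MAY_PREVENT = NDFRT["may_prevent"]
CI_WITH = NDFRT["CI_with"]
NDFRT_PROPERTIES = {"may_treat": MAY_TREAT, "may_prevent": MAY_PREVENT,
                    "CI_with": CI_WITH}

# Wikidata-like identifier properties (ATC code, UMLS CUI, RxNorm CUI) and
# drug relations.  Relations are keyed by label; the numeric IDs are only a
# naming convention on the fixture IRIs.
WDT_ATC = WDT["P267"]
WDT_CUI = WDT["P2892"]
WDT_RXNORM = WDT["P3345"]
WIKIDATA_RELATIONS = {
    "role": WDT["P2868"],          # subject has role
    "interaction": WDT["P2175"],   # significant drug interaction
    "condition": WDT["P769"],      # medical condition treated
}

# Seed category roots of the medical-domain constraint.
SEED_CATEGORY_LABELS = (
    "disease", "health", "medical genetics", "medicine", "urgency",
    "treatment", "anatomy", "addiction", "bacteria",
)

# Type constraint: classes an equivalent (sameAs) entity may carry.
DEFAULT_ALLOWED_CLASSES = (
    DBO["Disease"],
    DBO["Bacteria"],
    YAGO["WikicatViruses"],
    YAGO["WikicatRetroviruses"],
    YAGO["WikicatSurgicalProcedures"],
    YAGO["WikicatSurgicalRemovalProcedures"],
)

GRAPH_NAMES = ("ATC", "ICPC2", "NDFRT", "WIKIDATA", "DBPEDIA")


class ConfigurationError(ValueError):
    """Raised when a generator spec or run configuration is invalid."""


def normalize(text: str) -> str:
    """NFC-normalize and casefold a surface string (accents preserved)."""
    return unicodedata.normalize("NFC", text).casefold()


@dataclass(frozen=True)
class ConceptInfo:
    """A candidate DBpedia-like concept: one category reachable through one
    annotated entity, with one or more surface forms (synonyms)."""

    category: URIRef
    label: str
    entity: URIRef
    surfaces: tuple[str, ...]
    kind: str  # "signal" | "noise"


@dataclass
class FixtureSpec:
    """Sizes and seed for :func:`generate_kg_fixture`."""

    n_signal_concepts: int = 5
    n_noise_concepts: int = 30
    n_synonyms: int = 4
    n_drugs: int = 8
    n_icpc2_codes: int = 10
    abbreviate: bool = True
    include_worked_examples: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_signal_concepts < 0 or self.n_noise_concepts < 0:
            raise ConfigurationError("concept counts must be >= 0")
        if self.n_synonyms < 1:
            raise ConfigurationError("need at least one surface form per concept")
        if self.n_drugs < 1:
            raise ConfigurationError("need at least one random ATC drug chain")
        if self.n_icpc2_codes < 1:
            raise ConfigurationError("need at least one ICPC-2 code")


@dataclass
class KnowledgeFixture:
    """Named RDF graphs plus the surface-form dictionary.

    ``surface_forms`` maps normalized surface strings (including the
    abbreviated variants) to entity IRIs; ``abbreviations`` maps an
    abbreviation key to its expansion so the dictionary annotator can also
    expand-then-match.
    """

    graphs: dict[str, Graph]
    surface_forms: dict[str, URIRef]
    abbreviations: dict[str, str]
    seed_categories: list[URIRef]
    allowed_classes: list[URIRef]
    signal_concepts: list[ConceptInfo] = field(default_factory=list)
    noise_concepts: list[ConceptInfo] = field(default_factory=list)
    atc_leaf_codes: list[str] = field(default_factory=list)
    icpc2_codes: list[str] = field(default_factory=list)

    @property
    def concept_pool(self) -> list[ConceptInfo]:
        return list(self.signal_concepts) + list(self.noise_concepts)

    # -- persistence (Turtle per graph + one JSON sidecar) -----------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, g in self.graphs.items():
            g.serialize(destination=str(directory / f"{name.lower()}.ttl"),
                        format="turtle")
        meta = {
            "surface_forms": {s: str(i) for s, i in self.surface_forms.items()},
            "abbreviations": dict(self.abbreviations),
            "seed_categories": [str(c) for c in self.seed_categories],
            "allowed_classes": [str(c) for c in self.allowed_classes],
            "signal_concepts": [_concept_to_json(c) for c in self.signal_concepts],
            "noise_concepts": [_concept_to_json(c) for c in self.noise_concepts],
            "atc_leaf_codes": list(self.atc_leaf_codes),
            "icpc2_codes": list(self.icpc2_codes),
        }
        (directory / "fixture.json").write_text(
            json.dumps(meta, indent=2, ensure_ascii=False, sort_keys=True),
            encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "KnowledgeFixture":
        directory = Path(directory)
        graphs = {}
        for name in GRAPH_NAMES:
            g = Graph()
            g.parse(str(directory / f"{name.lower()}.ttl"), format="turtle")
            graphs[name] = g
        meta = json.loads((directory / "fixture.json").read_text(encoding="utf-8"))
        return cls(
            graphs=graphs,
            surface_forms={s: URIRef(i) for s, i in meta["surface_forms"].items()},
            abbreviations=dict(meta["abbreviations"]),
            seed_categories=[URIRef(c) for c in meta["seed_categories"]],
            allowed_classes=[URIRef(c) for c in meta["allowed_classes"]],
            signal_concepts=[_concept_from_json(c) for c in meta["signal_concepts"]],
            noise_concepts=[_concept_from_json(c) for c in meta["noise_concepts"]],
            atc_leaf_codes=list(meta["atc_leaf_codes"]),
            icpc2_codes=list(meta["icpc2_codes"]),
        )


def _concept_to_json(c: ConceptInfo) -> dict:
    return {"category": str(c.category), "label": c.label,
            "entity": str(c.entity), "surfaces": list(c.surfaces),
            "kind": c.kind}


def _concept_from_json(d: dict) -> ConceptInfo:
    return ConceptInfo(category=URIRef(d["category"]), label=d["label"],
                       entity=URIRef(d["entity"]),
                       surfaces=tuple(d["surfaces"]), kind=d["kind"])


# --- worked-example content ----------------------------------------------

def _add_atc_chain(g: Graph, codes_and_labels: list[tuple[str, str]],
                   cui: str | None = None) -> None:
    """Add a leaf-to-root ATC subclass chain; the first entry is the leaf."""
    nodes = [ATC[code] for code, _ in codes_and_labels]
    for (code, label), node in zip(codes_and_labels, nodes):
        g.add((node, SKOS.notation, Literal(code)))
        g.add((node, SKOS.prefLabel, Literal(label)))
    for child, parent in zip(nodes, nodes[1:]):
        g.add((child, RDFS.subClassOf, parent))
    if cui is not None:
        g.add((nodes[0], CUI_PROP, Literal(cui)))


def _populate_worked_examples(graphs: dict[str, Graph],
                              surface_forms: dict[str, URIRef],
                              seed_cats: dict[str, URIRef]) -> None:
    atc, icpc, ndfrt, wd, dbp = (graphs[n] for n in GRAPH_NAMES)

    # Tenitramine: C01DA38 -> C01DA -> C01D -> C01.
    _add_atc_chain(atc, [
        ("C01DA38", "tenitramine"),
        ("C01DA", "Organic nitrates used in cardiac disease"),
        ("C01D", "VASODILATORS USED IN CARDIAC DISEASES"),
        ("C01", "CARDIAC THERAPY DRUGS"),
    ])

    # Atorvastatin (Tahor): ATC C10AA05, linked to NDF-RT through its CUI.
    _add_atc_chain(atc, [
        ("C10AA05", "atorvastatin"),
        ("C10AA", "HMG CoA reductase inhibitors"),
        ("C10A", "LIPID MODIFYING AGENTS, PLAIN"),
        ("C10", "LIPID MODIFYING AGENTS"),
    ], cui="C0286651")

    drug = NDFRT["atorvastatin"]
    ndfrt.add((drug, CUI_PROP, Literal("C0286651")))
    ndfrt.add((drug, SKOS.prefLabel, Literal("Atorvastatin")))
    for prop, obj_label in ((CI_WITH, "Pregnancy"),
                            (MAY_TREAT, "Hypercholesterolemia"),
                            (MAY_PREVENT, "Cardiovascular disease")):
        obj = NDFRT[obj_label.replace(" ", "_")]
        ndfrt.add((obj, SKOS.prefLabel, Literal(obj_label)))
        ndfrt.add((drug, prop, obj))

    # Wikidata-like node for atorvastatin, resolvable by all three ids.
    wnode = WD["Q123"]
    wd.add((wnode, WDT_ATC, Literal("C10AA05")))
    wd.add((wnode, WDT_CUI, Literal("C0286651")))
    wd.add((wnode, WDT_RXNORM, Literal("83367")))
    wd.add((wnode, SKOS.prefLabel, Literal("atorvastatin")))
    for rel, obj_label in (("condition", "hypercholesterolemia"),
                           ("interaction", "ciclosporin"),
                           ("role", "statin")):
        obj = WD[obj_label]
        wd.add((obj, SKOS.prefLabel, Literal(obj_label)))
        wd.add((wnode, WIKIDATA_RELATIONS[rel], obj))

    # ICPC-2: heart failure K77 under chapter K.
    for code, label, parent in (("K77", "Heart failure", "K"),
                                ("R96", "Asthma", "R")):
        chapter = ICPC[parent]
        icpc.add((chapter, SKOS.prefLabel, Literal(f"Chapter {parent}")))
        icpc.add((chapter, SKOS.notation, Literal(parent)))
        node = ICPC[code]
        icpc.add((node, SKOS.notation, Literal(code)))
        icpc.add((node, SKOS.prefLabel, Literal(label)))
        icpc.add((node, RDFS.subClassOf, chapter))

    # DBpedia-like: "insuffisance cardiaque" with two medical categories,
    # "kyste" with one.
    def _category(label: str, seed_label: str) -> URIRef:
        cat = DBC[label.replace(" ", "_")]
        dbp.add((cat, SKOS.prefLabel, Literal(label)))
        dbp.add((cat, SKOS.broader, seed_cats[seed_label]))
        return cat

    cat_organ = _category("Organ failure", "disease")
    cat_cardio = _category("Cardiovascular disease", "disease")
    cat_neo = _category("Neoplasm stubs", "disease")

    heart = DBR["Insuffisance_cardiaque"]
    dbp.add((heart, SKOS.prefLabel, Literal("insuffisance cardiaque")))
    dbp.add((heart, DCTERMS.subject, cat_organ))
    dbp.add((heart, DCTERMS.subject, cat_cardio))
    heart_en = DBR_EN["Heart_failure"]
    dbp.add((heart, OWL.sameAs, heart_en))
    dbp.add((heart_en, RDF.type, DBO["Disease"]))

    kyste = DBR["Kyste_(médecine)"]
    dbp.add((kyste, SKOS.prefLabel, Literal("kyste")))
    dbp.add((kyste, DCTERMS.subject, cat_neo))
    kyste_en = DBR_EN["Cyst"]
    dbp.add((kyste, OWL.sameAs, kyste_en))
    dbp.add((kyste_en, RDF.type, DBO["Disease"]))

    surface_forms[normalize("insuffisance cardiaque")] = heart
    surface_forms[normalize("insuf cardiaque")] = heart  # abbreviated form
    surface_forms[normalize("kyste")] = kyste


# --- random population ----------------------------------------------------

_ATC_LETTERS = "ABCDGHJLMNPRSV"


def _random_atc_code(rng: np.random.Generator) -> str:
    return (
        rng.choice(list(_ATC_LETTERS))
        + f"{rng.integers(1, 17):02d}"
        + rng.choice(list(string.ascii_uppercase))
        + rng.choice(list(string.ascii_uppercase))
        + f"{rng.integers(1, 100):02d}"
    )


def generate_kg_fixture(spec: FixtureSpec | None = None) -> KnowledgeFixture:
    """Build a :class:`KnowledgeFixture` from *spec* (reproducible by seed)."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    graphs = {name: Graph() for name in GRAPH_NAMES}
    atc, icpc, ndfrt, wd, dbp = (graphs[n] for n in GRAPH_NAMES)
    surface_forms: dict[str, URIRef] = {}
    abbreviations: dict[str, str] = {}

    # Seed categories (medical-domain roots).
    seed_cats: dict[str, URIRef] = {}
    for label in SEED_CATEGORY_LABELS:
        cat = DBC["seed_" + label.replace(" ", "_")]
        dbp.add((cat, SKOS.prefLabel, Literal(label)))
        seed_cats[label] = cat

    atc_leaves: list[str] = []
    icpc2_codes: list[str] = []
    if spec.include_worked_examples:
        abbreviations["insuf"] = "insuffisance"
        _populate_worked_examples(graphs, surface_forms, seed_cats)
        atc_leaves += ["C01DA38", "C10AA05"]
        icpc2_codes += ["K77", "R96"]

    # Random ATC drug chains with CUIs, NDF-RT and Wikidata counterparts.
    seen_codes = set(atc_leaves)
    for i in range(spec.n_drugs):
        code = _random_atc_code(rng)
        while code in seen_codes:
            code = _random_atc_code(rng)
        seen_codes.add(code)
        chain = [(code, f"drug{i}"), (code[:5], f"group{i}l3"),
                 (code[:4], f"group{i}l2"), (code[:3], f"group{i}l1"),
                 (code[:1], f"group{i}l0")]
        cui = f"C{rng.integers(0, 10**7):07d}"
        _add_atc_chain(atc, chain, cui=cui)
        atc_leaves.append(code)

        # NDF-RT node for ~half of the drugs.
        if i % 2 == 0:
            drug = NDFRT[f"drug{i}"]
            ndfrt.add((drug, CUI_PROP, Literal(cui)))
            ndfrt.add((drug, SKOS.prefLabel, Literal(f"drug{i}")))
            n_rel = int(rng.integers(1, 4))
            all_props = list(NDFRT_PROPERTIES.values())
            idx = rng.permutation(len(all_props))[:n_rel]
            for j, prop in enumerate(all_props[i] for i in idx):
                obj = NDFRT[f"condition_{i}_{j}"]
                ndfrt.add((obj, SKOS.prefLabel, Literal(f"condition {i} {j}")))
                ndfrt.add((drug, prop, obj))

        # Wikidata node for ~half, resolvable by a random subset of ids.
        if i % 2 == 1:
            wnode = WD[f"Q{1000 + i}"]
            wd.add((wnode, SKOS.prefLabel, Literal(f"drug{i}")))
            id_choices = rng.random(3)
            if id_choices[0] < 0.7:
                wd.add((wnode, WDT_ATC, Literal(code)))
            if id_choices[1] < 0.7:
                wd.add((wnode, WDT_CUI, Literal(cui)))
            if id_choices[2] < 0.7 or (id_choices[:2] >= 0.7).all():
                wd.add((wnode, WDT_RXNORM, Literal(str(10000 + i))))
            for rel_name, rel in WIKIDATA_RELATIONS.items():
                if rng.random() < 0.6:
                    obj = WD[f"obj_{rel_name}_{i}"]
                    wd.add((obj, SKOS.prefLabel,
                            Literal(f"{rel_name} target {i}")))
                    wd.add((wnode, rel, obj))

    # ICPC-2 random codes, each with exactly one chapter parent.
    chapters = "ABDFHKLNPRSTUWXYZ"
    for i in range(spec.n_icpc2_codes):
        ch = chapters[int(rng.integers(0, len(chapters)))]
        code = f"{ch}{rng.integers(1, 100):02d}"
        while code in icpc2_codes:
            code = f"{ch}{rng.integers(1, 100):02d}"
        chapter = ICPC[ch]
        icpc.add((chapter, SKOS.prefLabel, Literal(f"Chapter {ch}")))
        icpc.add((chapter, SKOS.notation, Literal(ch)))
        node = ICPC[code]
        icpc.add((node, SKOS.notation, Literal(code)))
        icpc.add((node, SKOS.prefLabel, Literal(f"problem {code}")))
        icpc.add((node, RDFS.subClassOf, chapter))
        icpc2_codes.append(code)

    # Signal and noise DBpedia-like concepts.  Each concept is one category
    # reached through one entity carrying several synonym surface forms; the
    # category chains into a random seed category (constraint 1) and the
    # entity is sameAs-linked to a typed English node (constraint 2).
    def _make_concept(i: int, kind: str) -> ConceptInfo:
        tag = "sig" if kind == "signal" else "noise"
        label = f"{tag} category {i}"
        cat = DBC[f"{tag}_cat_{i}"]
        dbp.add((cat, SKOS.prefLabel, Literal(label)))
        # broader chain of depth 1-3 up to a seed category
        depth = int(rng.integers(1, 4))
        seed_label = SEED_CATEGORY_LABELS[
            int(rng.integers(0, len(SEED_CATEGORY_LABELS)))]
        upper = seed_cats[seed_label]
        node = cat
        for d in range(depth - 1):
            mid = DBC[f"{tag}_cat_{i}_up{d}"]
            dbp.add((node, SKOS.broader, mid))
            node = mid
        dbp.add((node, SKOS.broader, upper))

        ent = DBR[f"{tag}_ent_{i}"]
        surfaces = tuple(f"{tag}term{i}{c}"
                         for c in string.ascii_lowercase[:spec.n_synonyms])
        dbp.add((ent, SKOS.prefLabel, Literal(surfaces[0])))
        dbp.add((ent, DCTERMS.subject, cat))
        en = DBR_EN[f"{tag}_ent_{i}_en"]
        dbp.add((ent, OWL.sameAs, en))
        klass = DEFAULT_ALLOWED_CLASSES[
            int(rng.integers(0, len(DEFAULT_ALLOWED_CLASSES)))]
        dbp.add((en, RDF.type, klass))
        for j, s in enumerate(surfaces):
            surface_forms[normalize(s)] = ent
            if spec.abbreviate:
                abbrev = f"{tag[0]}g{i}{string.ascii_lowercase[j]}"
                abbreviations[abbrev] = s
                surface_forms[normalize(abbrev)] = ent
        return ConceptInfo(category=cat, label=label, entity=ent,
                           surfaces=surfaces, kind=kind)

    signal = [_make_concept(i, "signal") for i in range(spec.n_signal_concepts)]
    noise = [_make_concept(i, "noise") for i in range(spec.n_noise_concepts)]

    return KnowledgeFixture(
        graphs=graphs,
        surface_forms=surface_forms,
        abbreviations=abbreviations,
        seed_categories=list(seed_cats.values()),
        allowed_classes=list(DEFAULT_ALLOWED_CLASSES),
        signal_concepts=signal,
        noise_concepts=noise,
        atc_leaf_codes=atc_leaves,
        icpc2_codes=icpc2_codes,
    )
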