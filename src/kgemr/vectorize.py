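"""Bag-of-words / bag-of-concepts vectorization and the feature-set registry.

A patient's representation is the concatenation x = V ⊕ C of a field-prefixed
bag-of-words V (raw token counts over the aggregated record text) and a
bag-of-concepts C (occurrence counts of knowledge-graph concept atoms).  The
registry maps the notation of the evaluated feature-set variants (baseline,
+t, +c1, +c1-2, +c2, +d_*, +w*, +s family) to their extraction sources,
field scopes and selection modes.

Aggregation rule: hospitalized patients contribute their static texts plus
only the consultations that precede the hospitalization; non-hospitalized
patients contribute everything.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from .cohort import PatientRecord
from .extract import ExtractionResult, extract_all
from .fields import (FIELD_PREFIXES, FULL_SCOPE, S_STAR_SCOPE, validate_scope)
from .fixtures import ConfigurationError, KnowledgeFixture, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSetSpec",
    "DesignMatrix",
    "tokenize",
    "build_bow",
    "build_boc",
    "concat",
    "assemble_design_matrix",
    "feature_set_spec",
    "variant_names",
    "annotation_whitelist",
    "MANUAL_CONCEPTS",
]

# The 14 manually curated medical-domain concepts used by the +s / +s*
# variants (severe-pathology categories).
MANUAL_CONCEPTS: tuple[str, ...] = (
    "Neoplasm stubs", "Oncology", "Radiation therapy",
    "Cardiovascular disease", "Cardiac arrhythmia",
    "Neurovascular disease",
    "Malignant hemopathy", "Autoimmune disease",
    "Medical condition related to obesity",
    "Genetic diseases and disorders",
    "Surgical removal procedures", "Organ failure",
    "Medical emergencies", "Cardiac emergencies",
)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A registered feature-set variant.

    ``field_scope`` governs concept extraction from free text; the word
    block always uses the full field set so that the V-block is identical
    across variants and comparisons differ only in the C-block.
    """

    name: str
    sources: frozenset[str] = frozenset()
    field_scope: tuple[str, ...] = FULL_SCOPE
    word_scope: tuple[str, ...] = FULL_SCOPE
    atc_levels: frozenset[int] = frozenset()
    ndfrt_properties: tuple[str, ...] = ()
    wikidata_relations: tuple[str, ...] = ()
    concept_whitelist: Optional[frozenset[str]] = None
    whitelist_source: Optional[str] = None  # how ∩/∪ whitelists are derived
    selection_mode: str = "none"  # none | manual_list | lasso
    annotator: Optional[Callable] = None

    def with_whitelist(self, labels) -> "FeatureSetSpec":
        return replace(self, concept_whitelist=frozenset(labels))


_REGISTRY: dict[str, FeatureSetSpec] = {}
_ALIASES = {
    "+c1-2": "+c1−2",
    "+s*and": "+s*∩", "+s*or": "+s*∪",
    "+sm_inter": "+sm∩", "+sm_union": "+sm∪",
}


def _register(spec: FeatureSetSpec) -> None:
    _REGISTRY[spec.name] = spec


_register(FeatureSetSpec(name="baseline"))
_register(FeatureSetSpec(name="+t", sources=frozenset({"ICPC2"})))
for _name, _levels in (("+c1", {1}), ("+c1−2", {1, 2}), ("+c2", {2})):
    _register(FeatureSetSpec(name=_name, sources=frozenset({"ATC"}),
                             atc_levels=frozenset(_levels)))
for _prop in ("prevent", "treat", "CI"):
    _full = {"prevent": "may_prevent", "treat": "may_treat",
             "CI": "CI_with"}[_prop]
    _register(FeatureSetSpec(name=f"+d_{_prop}", sources=frozenset({"NDFRT"}),
                             ndfrt_properties=(_full,)))
for _suffix, _rel in (("a", "role"), ("i", "interaction"), ("m", "condition")):
    _register(FeatureSetSpec(name=f"+w{_suffix}",
                             sources=frozenset({"WIKIDATA"}),
                             wikidata_relations=(_rel,)))
# DBpedia family.  +s uses all text fields; the +s* family restricts to the
# patient's own record (drops family history, past problems, symptoms).
_register(FeatureSetSpec(name="+s", sources=frozenset({"DBPEDIA"}),
                         field_scope=FULL_SCOPE,
                         concept_whitelist=frozenset(MANUAL_CONCEPTS),
                         selection_mode="manual_list"))
_register(FeatureSetSpec(name="+s*", sources=frozenset({"DBPEDIA"}),
                         field_scope=S_STAR_SCOPE,
                         concept_whitelist=frozenset(MANUAL_CONCEPTS),
                         selection_mode="manual_list"))
_register(FeatureSetSpec(name="+s*T", sources=frozenset({"DBPEDIA"}),
                         field_scope=S_STAR_SCOPE))
# Human-annotation-derived subsets.  Following the source notation, the
# ∩ variant keeps concepts judged relevant by at least one annotator and the
# ∪ variant those judged relevant by all annotators; the whitelist is
# supplied at run time from an AnnotationMatrix.
_register(FeatureSetSpec(name="+s*∩", sources=frozenset({"DBPEDIA"}),
                         field_scope=S_STAR_SCOPE,
                         selection_mode="manual_list",
                         whitelist_source="annotations_any"))
_register(FeatureSetSpec(name="+s*∪", sources=frozenset({"DBPEDIA"}),
                         field_scope=S_STAR_SCOPE,
                         selection_mode="manual_list",
                         whitelist_source="annotations_all"))
_register(FeatureSetSpec(name="+s*m", sources=frozenset({"DBPEDIA"}),
                         field_scope=S_STAR_SCOPE, selection_mode="lasso"))
_register(FeatureSetSpec(name="+sm", sources=frozenset({"DBPEDIA"}),
                         field_scope=FULL_SCOPE, selection_mode="lasso"))
_register(FeatureSetSpec(name="+sm∩", sources=frozenset({"DBPEDIA"}),
                         field_scope=FULL_SCOPE, selection_mode="manual_list",
                         whitelist_source="fold_intersection"))
_register(FeatureSetSpec(name="+sm∪", sources=frozenset({"DBPEDIA"}),
                         field_scope=FULL_SCOPE, selection_mode="manual_list",
                         whitelist_source="fold_union"))


def feature_set_spec(name: str) -> FeatureSetSpec:
    """Look up a registered variant (ASCII aliases accepted)."""
    key = _ALIASES.get(name, name)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(f"unknown feature-set variant {name!r}; known: "
                       f"{sorted(_REGISTRY)}") from None


def variant_names() -> list[str]:
    return list(_REGISTRY)


def annotation_whitelist(annotations, mode: str) -> frozenset[str]:
    """Concept labels judged relevant by annotators.

    ``mode='any'`` keeps concepts marked relevant by at least one
    annotator, ``mode='all'`` only those marked relevant by every
    annotator (missing cells count as not-relevant).  Feed the result to
    :meth:`FeatureSetSpec.with_whitelist` for the annotation-derived
    variants.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    rows = [[cell == "relevant" for cell in row]
            for row in annotations.cells]
    agg = (any if mode == "any" else all)
    return frozenset(
        concept for j, concept in enumerate(annotations.universe)
        if agg(row[j] for row in rows))


# --- tokenization and bags ------------------------------------------------

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Unicode word tokens of length >= 2 after NFC + casefold; digits kept,
    hyphenated compounds split, accents preserved."""
    return [t for t in _WORD_RE.findall(normalize(text)) if len(t) >= 2]


def build_bow(record: PatientRecord, field_scope=FULL_SCOPE) -> Counter:
    """Field-prefixed token counts over the aggregated record text."""
    scope = validate_scope(field_scope)
    counts: Counter = Counter()
    for f in scope:
        prefix = FIELD_PREFIXES[f]
        if f in record.static_texts:
            for tok in tokenize(record.static_texts[f]):
                counts[f"{prefix}:{tok}"] += 1
    for c in record.contributing_consultations():
        for f in scope:
            if f in c.field_texts:
                prefix = FIELD_PREFIXES[f]
                for tok in tokenize(c.field_texts[f]):
                    counts[f"{prefix}:{tok}"] += 1
    return counts


def build_boc(extraction: ExtractionResult) -> Counter:
    """Concept-feature counts: one column per distinct
    (source, property, concept)."""
    counts: Counter = Counter()
    for atom, n in extraction.atoms.items():
        if n < 1:
            raise ValueError("atom counts must be >= 1")
        counts[atom.feature_name] += n
    return counts


def concat(V: Counter, C: Counter) -> Counter:
    """x = V ⊕ C; the two column namespaces must be disjoint."""
    overlap = set(V) & set(C)
    if overlap:
        raise ValueError(f"word/concept namespace collision: {sorted(overlap)[:5]}")
    out = Counter(V)
    out.update(C)
    return out


@dataclass
class DesignMatrix:
    """Sparse patient x feature count matrix, V-block then C-block."""

    X: sp.csr_matrix
    row_ids: list[str]
    col_names: list[str]
    boundary: int  # first C-block column index

    @property
    def word_columns(self) -> list[str]:
        return self.col_names[:self.boundary]

    @property
    def concept_columns(self) -> list[str]:
        return self.col_names[self.boundary:]

    def concept_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.col_names), dtype=bool)
        mask[self.boundary:] = True
        return mask

    def restrict_concepts(self, keep_labels) -> "DesignMatrix":
        """Keep all word columns and only the named concept columns."""
        keep = set(keep_labels)
        idx = list(range(self.boundary)) + [
            i for i in range(self.boundary, len(self.col_names))
            if self.col_names[i] in keep]
        return DesignMatrix(X=sp.csr_matrix(self.X[:, idx]),
                            row_ids=list(self.row_ids),
                            col_names=[self.col_names[i] for i in idx],
                            boundary=self.boundary)

    def save(self, directory) -> None:
        from pathlib import Path
        import scipy.io as sio
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(str(directory / "design.mtx"), self.X)
        (directory / "rows.tsv").write_text(
            "\n".join(self.row_ids) + "\n", encoding="utf-8")
        (directory / "cols.tsv").write_text(
            "\n".join(f"{n}\t{int(i >= self.boundary)}"
                      for i, n in enumerate(self.col_names)) + "\n",
            encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "DesignMatrix":
        from pathlib import Path
        import scipy.io as sio
        directory = Path(directory)
        X = sp.csr_matrix(sio.mmread(str(directory / "design.mtx")))
        row_ids = (directory / "rows.tsv").read_text(
            encoding="utf-8").rstrip("\n").split("\n")
        cols, flags = [], []
        for line in (directory / "cols.tsv").read_text(
                encoding="utf-8").rstrip("\n").split("\n"):
            name, flag = line.rsplit("\t", 1)
            cols.append(name)
            flags.append(int(flag))
        boundary = flags.index(1) if 1 in flags else len(cols)
        return cls(X=X, row_ids=row_ids, col_names=cols, boundary=boundary)


def assemble_design_matrix(cohort: list[PatientRecord],
                           fixture: KnowledgeFixture | None,
                           variant: FeatureSetSpec | str
                           ) -> tuple[DesignMatrix, np.ndarray]:
    """Build the cohort design matrix and label vector for a variant.

    Hospitalized patients with ``hospitalization_index == 0`` carry no
    pre-hospitalization evidence and are excluded with a warning.
    """
    if isinstance(variant, str):
        variant = feature_set_spec(variant)
    if variant.sources and fixture is None:
        raise ConfigurationError(f"variant {variant.name} needs a fixture")
    if (variant.selection_mode == "manual_list"
            and variant.concept_whitelist is None):
        raise ConfigurationError(
            f"variant {variant.name} needs a concept whitelist "
            f"({variant.whitelist_source}); derive one with "
            "annotation_whitelist()/fold_union()/fold_intersection() and "
            "apply it with FeatureSetSpec.with_whitelist()")

    rows: list[tuple[str, Counter, Counter, bool]] = []
    for record in cohort:
        if record.hospitalized and record.hospitalization_index == 0:
            logger.warning("excluding %s: hospitalization before any "
                           "consultation", record.patient_id)
            continue
        V = build_bow(record, variant.word_scope)
        if variant.sources:
            C = build_boc(extract_all(record, fixture, variant))
        else:
            C = Counter()
        rows.append((record.patient_id, V, C, record.hospitalized))

    word_vocab = sorted(set().union(*(set(V) for _, V, _, _ in rows))
                        if rows else set())
    concept_vocab = sorted(set().union(*(set(C) for _, _, C, _ in rows))
                           if rows else set())
    col_index = {name: j for j, name in
                 enumerate(word_vocab + concept_vocab)}
    boundary = len(word_vocab)

    data, indices, indptr = [], [], [0]
    row_ids, labels = [], []
    for pid, V, C, y in rows:
        x = concat(V, C)
        for name, value in x.items():
            indices.append(col_index[name])
            data.append(value)
        indptr.append(len(data))
        row_ids.append(pid)
        labels.append(y)
    X = sp.csr_matrix((np.asarray(data, dtype=np.float64), indices, indptr),
                      shape=(len(row_ids), len(col_index)))
    X.sort_indices()
    matrix = DesignMatrix(X=X, row_ids=row_ids,
                          col_names=word_vocab + concept_vocab,
                          boundary=boundary)
    return matrix, np.asarray(labels, dtype=int)
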