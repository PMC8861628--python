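"""Synthetic EMR cohort generator and simulated annotators.

The generator emulates a balanced primary-care cohort labelled for
hospitalization.  Each patient carries static free-text fields (personal and
family history, allergies, ...) and an ordered list of consultations with
free-text fields plus ATC drug codes and ICPC-2 problem codes.  The
hospitalization label is drawn from a logistic model whose linear predictor
sums planted log-odds weights over the *signal* concepts whose surface forms
were injected into the patient's texts; the cohort is then rebalanced to the
exact configured class counts by rejection sampling, mirroring a designed
balanced dataset rather than natural prevalence.

Signal (and noise) concepts enter the text through synonym surface forms,
optionally replaced by their abbreviation with probability
``abbreviation_rate``.  Because each concept has several synonyms, a
bag-of-words model sees the signal fragmented over synonym columns while the
concept features of the enriched representation aggregate them — the
property that makes knowledge-graph enrichment informative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdflib import URIRef

from .fields import ALL_FIELDS, CONSULTATION_FIELDS, STATIC_FIELDS
from .fixtures import ConfigurationError, KnowledgeFixture

__all__ = [
    "CohortConfig",
    "Consultation",
    "PatientRecord",
    "GroundTruth",
    "AnnotationMatrix",
    "generate_cohort",
    "simulate_annotators",
    "save_cohort",
    "load_cohort",
]


@dataclass
class CohortConfig:
    n_hospitalized: int = 714
    n_not_hospitalized: int = 732
    consultations_per_patient: tuple[int, int] = (3, 8)
    field_names: tuple[str, ...] = ALL_FIELDS
    vocab_size_words: int = 300
    n_signal_concepts: int = 5
    n_noise_concepts: int = 30
    effect_sizes: tuple[float, ...] | None = None  # default 2.0 per signal
    signal_exposure_rate: float = 0.3
    noise_exposure_rate: float = 0.3
    abbreviation_rate: float = 0.2
    codes_per_consultation: int = 2
    tokens_per_field: tuple[int, int] = (3, 8)
    seed: int = 0

    def resolved_effects(self) -> np.ndarray:
        if self.effect_sizes is None:
            return np.full(self.n_signal_concepts, 2.0)
        return np.asarray(self.effect_sizes, dtype=float)

    def validate(self) -> None:
        counts = (self.n_hospitalized, self.n_not_hospitalized,
                  self.vocab_size_words, self.n_signal_concepts,
                  self.n_noise_concepts)
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        for p in (self.signal_exposure_rate, self.noise_exposure_rate,
                  self.abbreviation_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        lo, hi = self.consultations_per_patient
        if lo < 1 or hi < lo:
            raise ConfigurationError("bad consultations_per_patient range")
        if len(self.resolved_effects()) != self.n_signal_concepts:
            raise ConfigurationError(
                "effect_sizes must have length n_signal_concepts")


@dataclass
class Consultation:
    order_index: int
    field_texts: dict[str, str]
    atc_codes: list[str] = field(default_factory=list)
    icpc2_codes: list[str] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    static_texts: dict[str, str]
    consultations: list[Consultation]
    hospitalized: bool
    hospitalization_index: int | None = None

    def __post_init__(self) -> None:
        if self.hospitalized and self.hospitalization_index is None:
            raise ValueError("hospitalized record needs hospitalization_index")
        if not self.hospitalized and self.hospitalization_index is not None:
            raise ValueError("non-hospitalized record cannot carry an index")
        if (self.hospitalization_index is not None
                and self.hospitalization_index > len(self.consultations)):
            raise ValueError("hospitalization_index beyond consultation range")

    def contributing_consultations(self) -> list[Consultation]:
        """Consultations that enter the patient's representation: everything
        for non-hospitalized patients, only pre-hospitalization visits
        otherwise."""
        if not self.hospitalized:
            return list(self.consultations)
        return [c for c in self.consultations
                if c.order_index < self.hospitalization_index]


@dataclass
class GroundTruth:
    """Planted generative parameters enabling parameter-recovery tests."""

    signal_concepts: dict[URIRef, float]  # category IRI -> log-odds weight
    intercept: float

    def to_json(self) -> dict:
        return {"signal_concepts": {str(k): v
                                    for k, v in self.signal_concepts.items()},
                "intercept": self.intercept}


@dataclass
class AnnotationMatrix:
    """Annotator x concept label matrix; cells are 'relevant', 'irrelevant'
    or None (missing, only allowed for human annotators)."""

    annotators: list[str]
    universe: list[str]
    cells: np.ndarray  # object array of shape (n_annotators, n_concepts)

    def row(self, annotator: str) -> np.ndarray:
        return self.cells[self.annotators.index(annotator)]


# --- generation -----------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _fill_text(rng: np.random.Generator, vocab: list[str],
               lo: int, hi: int) -> list[str]:
    n = int(rng.integers(lo, hi + 1))
    return [vocab[int(i)] for i in rng.integers(0, len(vocab), size=n)]


def generate_cohort(config: CohortConfig, fixture: KnowledgeFixture
                    ) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a labelled cohort with planted concept effects.

    Patients are drawn until the exact configured counts of hospitalized and
    non-hospitalized records are reached; the output is ordered hospitalized
    first, then non-hospitalized, with sequential patient ids.
    """
    config.validate()
    if config.n_signal_concepts > len(fixture.signal_concepts):
        raise ConfigurationError(
            f"config requests {config.n_signal_concepts} signal concepts but "
            f"fixture provides {len(fixture.signal_concepts)}")
    if config.n_noise_concepts > len(fixture.noise_concepts):
        raise ConfigurationError(
            f"config requests {config.n_noise_concepts} noise concepts but "
            f"fixture provides {len(fixture.noise_concepts)}")

    rng = np.random.default_rng(config.seed)
    signal = fixture.signal_concepts[:config.n_signal_concepts]
    noise = fixture.noise_concepts[:config.n_noise_concepts]
    effects = config.resolved_effects()
    # Centre the linear predictor so both classes are drawn efficiently.
    intercept = -config.signal_exposure_rate * float(effects.sum())
    truth = GroundTruth(
        signal_concepts={c.category: float(w) for c, w in zip(signal, effects)},
        intercept=intercept)

    vocab = [f"w{i}" for i in range(config.vocab_size_words)]
    surface_to_abbrev = {v: k for k, v in fixture.abbreviations.items()}

    need = {True: config.n_hospitalized, False: config.n_not_hospitalized}
    got: dict[bool, int] = {True: 0, False: 0}
    records: dict[bool, list[PatientRecord]] = {True: [], False: []}
    total = config.n_hospitalized + config.n_not_hospitalized
    max_attempts = 60 * (total + 10)

    attempts = 0
    while (got[True] < need[True] or got[False] < need[False]):
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "label rebalancing exceeded the attempt budget; "
                "check effect sizes and exposure rates")

        exposed_signal = rng.random(len(signal)) < config.signal_exposure_rate
        exposed_noise = rng.random(len(noise)) < config.noise_exposure_rate
        lp = intercept + float(effects[exposed_signal].sum())
        hospitalized = bool(rng.random() < _sigmoid(lp))

        n_cons = int(rng.integers(config.consultations_per_patient[0],
                                  config.consultations_per_patient[1] + 1))
        hosp_index = int(rng.integers(1, n_cons + 1)) if hospitalized else None
        # consultations (and statics) usable for injection
        usable = hosp_index if hospitalized else n_cons

        lo, hi = config.tokens_per_field
        consultations = []
        for k in range(n_cons):
            texts = {f: _fill_text(rng, vocab, lo, hi)
                     for f in CONSULTATION_FIELDS}
            atc = [fixture.atc_leaf_codes[int(i)] for i in rng.integers(
                0, len(fixture.atc_leaf_codes),
                size=int(rng.integers(0, config.codes_per_consultation + 1)))
            ] if fixture.atc_leaf_codes else []
            icpc = [fixture.icpc2_codes[int(i)] for i in rng.integers(
                0, len(fixture.icpc2_codes),
                size=int(rng.integers(0, config.codes_per_consultation + 1)))
            ] if fixture.icpc2_codes else []
            consultations.append(
                Consultation(order_index=k, field_texts=texts,
                             atc_codes=atc, icpc2_codes=icpc))
        statics = {f: _fill_text(rng, vocab, max(1, lo - 2), max(2, hi - 3))
                   for f in STATIC_FIELDS}

        # Inject surface forms of exposed concepts into usable text slots.
        for concept, exposed in (
                list(zip(signal, exposed_signal))
                + list(zip(noise, exposed_noise))):
            if not exposed:
                continue
            n_occ = int(rng.integers(1, 4))
            for _ in range(n_occ):
                surf = concept.surfaces[
                    int(rng.integers(0, len(concept.surfaces)))]
                if (surf in surface_to_abbrev
                        and rng.random() < config.abbreviation_rate):
                    surf = surface_to_abbrev[surf]
                if rng.random() < 0.25:  # static field
                    f = STATIC_FIELDS[int(rng.integers(0, len(STATIC_FIELDS)))]
                    statics[f].append(surf)
                else:
                    ci = int(rng.integers(0, usable))
                    f = CONSULTATION_FIELDS[
                        int(rng.integers(0, len(CONSULTATION_FIELDS)))]
                    consultations[ci].field_texts[f].append(surf)

        if got[hospitalized] >= need[hospitalized]:
            continue  # class already full: rejection step of the rebalancing

        for c in consultations:
            c.field_texts = {f: " ".join(toks)
                             for f, toks in c.field_texts.items()}
        record = PatientRecord(
            patient_id="",  # assigned after rebalancing
            static_texts={f: " ".join(toks) for f, toks in statics.items()},
            consultations=consultations,
            hospitalized=hospitalized,
            hospitalization_index=hosp_index)
        records[hospitalized].append(record)
        got[hospitalized] += 1

    out = records[True] + records[False]
    for i, r in enumerate(out):
        r.patient_id = f"P{i:05d}"
    return out, truth


# --- simulated annotators -------------------------------------------------

def simulate_annotators(universe: list[str], n_annotators: int,
                        agreement: float, seed: int = 0) -> AnnotationMatrix:
    """Each annotator copies a hidden truth label with probability
    *agreement* and flips it otherwise, giving direct control over expected
    pairwise agreement."""
    if n_annotators < 2:
        raise ValueError("at least 2 annotators are required")
    if not universe:
        raise ValueError("universe must be non-empty")
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = rng.random(len(universe)) < 0.5
    cells = np.empty((n_annotators, len(universe)), dtype=object)
    for a in range(n_annotators):
        keep = rng.random(len(universe)) < agreement
        labels = np.where(keep, truth, ~truth)
        cells[a] = np.where(labels, "relevant", "irrelevant")
    return AnnotationMatrix(
        annotators=[f"A_{i + 1}" for i in range(n_annotators)],
        universe=list(universe), cells=cells)


# --- persistence ----------------------------------------------------------

def save_cohort(records: list[PatientRecord], truth: GroundTruth,
                config: CohortConfig, directory: str | Path) -> None:
    """Write patients.tsv, consultations.tsv and ground_truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pat_cols = ["patient_id", "hospitalized", "hospitalization_index",
                *STATIC_FIELDS]
    lines = ["\t".join(pat_cols)]
    for r in records:
        idx = "" if r.hospitalization_index is None else str(
            r.hospitalization_index)
        lines.append("\t".join(
            [r.patient_id, str(int(r.hospitalized)), idx]
            + [r.static_texts.get(f, "") for f in STATIC_FIELDS]))
    (directory / "patients.tsv").write_text("\n".join(lines) + "\n",
                                            encoding="utf-8")

    cons_cols = ["patient_id", "order_index", *CONSULTATION_FIELDS,
                 "atc_codes", "icpc2_codes"]
    lines = ["\t".join(cons_cols)]
    for r in records:
        for c in r.consultations:
            lines.append("\t".join(
                [r.patient_id, str(c.order_index)]
                + [c.field_texts.get(f, "") for f in CONSULTATION_FIELDS]
                + [";".join(c.atc_codes), ";".join(c.icpc2_codes)]))
    (directory / "consultations.tsv").write_text("\n".join(lines) + "\n",
                                                 encoding="utf-8")

    payload = {"ground_truth": truth.to_json(),
               "config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in vars(config).items()}}
    (directory / "ground_truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def load_cohort(directory: str | Path) -> list[PatientRecord]:
    directory = Path(directory)
    cons_lines = (directory / "consultations.tsv").read_text(
        encoding="utf-8").rstrip("\n").split("\n")
    header = cons_lines[0].split("\t")
    consultations: dict[str, list[Consultation]] = {}
    for line in cons_lines[1:]:
        row = dict(zip(header, line.split("\t")))
        consultations.setdefault(row["patient_id"], []).append(Consultation(
            order_index=int(row["order_index"]),
            field_texts={f: row.get(f, "") for f in CONSULTATION_FIELDS},
            atc_codes=[c for c in row["atc_codes"].split(";") if c],
            icpc2_codes=[c for c in row["icpc2_codes"].split(";") if c]))
    for cons in consultations.values():
        cons.sort(key=lambda c: c.order_index)

    pat_lines = (directory / "patients.tsv").read_text(
        encoding="utf-8").rstrip("\n").split("\n")
    header = pat_lines[0].split("\t")
    records = []
    for line in pat_lines[1:]:
        row = dict(zip(header, line.split("\t")))
        hosp = bool(int(row["hospitalized"]))
        records.append(PatientRecord(
            patient_id=row["patient_id"],
            static_texts={f: row.get(f, "") for f in STATIC_FIELDS},
            consultations=consultations.get(row["patient_id"], []),
            hospitalized=hosp,
            hospitalization_index=(int(row["hospitalization_index"])
                                   if hosp else None)))
    return records
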