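"""End-to-end pipeline: generate -> extract/vectorize -> select -> evaluate.

A single YAML-serializable :class:`RunConfig` drives every stage; all
randomness is funnelled through one master seed from which per-stage seeds
are derived, so each stage is independently re-runnable.  Each run writes
its artifacts plus a manifest (seeds, sizes, SHA-256 hashes of outputs)
under a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig, generate_cohort, save_cohort
from .evaluate import (CVProtocol, EvaluationReport, compare_variants,
                       nested_cv, protocol_preset)
from .fixtures import FixtureSpec, generate_kg_fixture
from .metrics import avg_metrics
from .select import fold_intersection, fold_union
from .vectorize import assemble_design_matrix, feature_set_spec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report", "derive_seeds"]


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Derive *n* independent per-stage seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    out_dir: str = "kgemr_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    variants: tuple[str, ...] = ("baseline", "+sm")
    estimator: str = "lr"
    protocol: str = "screen"
    seed: int = 0
    derive_fold_set_variants: bool = True  # +sm∩ / +sm∪ after +sm

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("cohort", {}).items()})
        fixture = FixtureSpec(**raw.pop("fixture", {}))
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(cohort=cohort, fixture=fixture, **raw)

    def validate(self) -> None:
        for v in self.variants:
            feature_set_spec(v)  # raises on unknown names
        self.cohort.validate()
        self.fixture.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _report_json(rep: EvaluationReport) -> dict:
    return {
        "variant": rep.variant,
        "estimator": rep.estimator,
        "pooled_f": rep.pooled_f,
        "averages": {m: avg_metrics({m: rep.per_fold(m)})[m]
                     for m in ("precision", "recall", "f1", "auc")},
        "folds": [{
            "fold": f.fold_index, "tp": f.tp, "fp": f.fp, "fn": f.fn,
            "tn": f.tn, "precision": f.precision, "recall": f.recall,
            "f1": f.f1, "auc": f.auc, "best_params": f.best_params,
            "selected_concepts": (sorted(f.selection.selected_concepts)
                                  if f.selection else None),
        } for f in rep.folds],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the evaluation summary dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture_seed, cohort_seed, eval_seed = derive_seeds(config.seed, 3)

    # stage 1: knowledge fixture
    fspec = FixtureSpec(**{**vars(config.fixture), "seed": fixture_seed})
    fixture = generate_kg_fixture(fspec)
    fixture.save(out / "fixture")

    # stage 2: cohort
    ccfg = CohortConfig(**{**vars(config.cohort), "seed": cohort_seed})
    cohort, truth = generate_cohort(ccfg, fixture)
    save_cohort(cohort, truth, ccfg, out / "cohort")

    # stage 3-5: vectorize, select, evaluate per variant
    protocol = protocol_preset(config.protocol, seed=eval_seed)
    reports: dict[str, EvaluationReport] = {}
    matrices = {}
    for name in config.variants:
        spec = feature_set_spec(name)
        if spec.whitelist_source in ("fold_union", "fold_intersection"):
            continue  # derived after the lasso variant has run
        matrix, y = assemble_design_matrix(cohort, fixture, spec)
        matrix.save(out / "matrices" / name.replace("*", "star"))
        rep = nested_cv(matrix, y, protocol, estimator=config.estimator,
                        selection_mode=("lasso" if spec.selection_mode ==
                                        "lasso" else "none"))
        rep.variant = name
        reports[name] = rep
        matrices[name] = (matrix, y)

    # derived fold-set variants (+sm∩ / +sm∪) from a lasso variant's folds
    if config.derive_fold_set_variants:
        lasso_parent = next((n for n in reports
                             if feature_set_spec(n).selection_mode == "lasso"),
                            None)
        for name in config.variants:
            spec = feature_set_spec(name)
            if spec.whitelist_source not in ("fold_union",
                                             "fold_intersection"):
                continue
            if lasso_parent is None:
                logger.warning("skipping %s: no lasso variant in run", name)
                continue
            sels = reports[lasso_parent].selections
            keep = (fold_union(sels)
                    if spec.whitelist_source == "fold_union"
                    else fold_intersection(sels))
            parent_matrix, y = matrices[lasso_parent]
            matrix = parent_matrix.restrict_concepts(keep)
            rep = nested_cv(matrix, y, protocol,
                            estimator=config.estimator,
                            selection_mode="none")
            rep.variant = name
            reports[name] = rep

    summary = {
        "seeds": {"master": config.seed, "fixture": fixture_seed,
                  "cohort": cohort_seed, "evaluate": eval_seed},
        "protocol": vars(protocol),
        "reports": {n: _report_json(r) for n, r in reports.items()},
    }
    if "baseline" in reports:
        summary["comparisons"] = compare_variants(reports, "baseline")
    (out / "report.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    (out / "report.tsv").write_text(render_report(reports), encoding="utf-8")

    manifest = {
        "seeds": summary["seeds"],
        "n_patients": len(cohort),
        "variants": list(reports),
        "hashes": {str(p.relative_to(out)): _sha256(p)
                   for p in sorted(out.rglob("*"))
                   if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    summary["manifest"] = manifest
    return summary


def render_report(reports: dict[str, EvaluationReport]) -> str:
    """Render a per-variant metric table (TSV) with pooled F, per-fold
    averages and sample standard deviations, 4 decimal places."""
    header = ["features_set", "pooled_F", "PR_avg", "RE_avg", "F1_avg",
              "AUC_avg", "STD(PR)", "STD(RE)", "STD(F1)", "STD(AUC)"]
    lines = ["\t".join(header)]
    for name, rep in reports.items():
        stats = {m: avg_metrics({m: rep.per_fold(m)})[m]
                 for m in ("precision", "recall", "f1", "auc")}
        lines.append("\t".join(
            [name, f"{rep.pooled_f:.4f}"]
            + [f"{stats[m][0]:.4f}" for m in ("precision", "recall",
                                              "f1", "auc")]
            + [f"{stats[m][1]:.4f}" for m in ("precision", "recall",
                                              "f1", "auc")]))
    return "\n".join(lines) + "\n"
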