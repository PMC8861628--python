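"""Nested cross-validation experiment runner.

The outer loop is a stratified K-fold over patients; within each outer
training set, hyperparameters are chosen by random search scored with mean
F1 over L stratified inner folds (first-best tie-break), and — for
lasso-selected variants — the concept columns are first filtered by
L1-penalized selection on the same training data.  Per-fold confusion
counts, precision/recall/F1/AUC, chosen hyperparameters and selected
concept sets are returned for downstream pooling, averaging and paired
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (f1_score, precision_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .metrics import FoldCounts, corrected_ttest, f_tp_fp
from .select import FoldSelection, lasso_select
from .vectorize import DesignMatrix

__all__ = [
    "CVProtocol",
    "FoldResult",
    "EvaluationReport",
    "nested_cv",
    "compare_variants",
    "PROTOCOL_PRESETS",
]


@dataclass
class CVProtocol:
    """Nested-CV shape: K outer folds, L inner folds, n_iter random-search
    draws.  Presets: 'screen' (K=10, L=2, 7 iterations) and 'strict'
    (K=10, L=3, 150 iterations)."""

    K: int = 10
    L: int = 3
    n_iter: int = 150
    inner_selection_folds: int | None = None  # defaults to L
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2 or self.L < 2 or self.n_iter < 1:
            raise ValueError("require K >= 2, L >= 2, n_iter >= 1")


PROTOCOL_PRESETS = {
    "screen": dict(K=10, L=2, n_iter=7),
    "strict": dict(K=10, L=3, n_iter=150),
    "toy": dict(K=5, L=2, n_iter=3),
}


def protocol_preset(name: str, seed: int = 0) -> CVProtocol:
    try:
        kwargs = PROTOCOL_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown protocol preset {name!r}") from None
    return CVProtocol(seed=seed, **kwargs)


# --- hyperparameter spaces ------------------------------------------------

def _sample_params(estimator: str, rng: np.random.Generator) -> dict:
    if estimator == "lr":
        return {"C": float(rng.exponential(1.0)),
                "penalty": str(rng.choice(["l1", "l2"]))}
    if estimator == "svc":
        return {"C": float(rng.exponential(1.0)),
                "kernel": str(rng.choice(["linear", "rbf", "poly"])),
                "gamma": float(rng.exponential(1.0))}
    if estimator == "rf":
        return {"n_estimators": int(rng.integers(10, 501)),
                "max_depth": int(rng.integers(5, 31)),
                "min_samples_split": int(rng.integers(2, 31)),
                "min_samples_leaf": int(rng.integers(1, 6)),
                "max_leaf_nodes": int(rng.integers(10, 51))}
    raise ValueError(f"unknown estimator {estimator!r}")


def _build_estimator(estimator: str, params: dict, seed: int):
    if estimator == "lr":
        # the search space names penalties l1/l2; newer scikit-learn wants
        # the elastic-net mixing ratio instead
        l1_ratio = 1.0 if params["penalty"] == "l1" else 0.0
        return LogisticRegression(solver="liblinear", max_iter=1000,
                                  C=params["C"], l1_ratio=l1_ratio,
                                  random_state=seed)
    if estimator == "svc":
        return SVC(random_state=seed, **params)
    if estimator == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown estimator {estimator!r}")


def _scores(model, X) -> np.ndarray:
    """Continuous scores for AUC: decision function for margin classifiers,
    positive-class probability otherwise."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X))
    return np.asarray(model.predict_proba(X))[:, 1]


@dataclass
class FoldResult:
    fold_index: int
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    auc: float
    best_params: dict
    selection: FoldSelection | None = None


@dataclass
class EvaluationReport:
    variant: str
    estimator: str
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def fold_counts(self) -> FoldCounts:
        return FoldCounts(tp=[f.tp for f in self.folds],
                          fp=[f.fp for f in self.folds],
                          fn=[f.fn for f in self.folds],
                          tn=[f.tn for f in self.folds])

    @property
    def pooled_f(self) -> float:
        return f_tp_fp(self.fold_counts)

    def per_fold(self, metric: str) -> list[float]:
        return [getattr(f, metric) for f in self.folds]

    @property
    def selections(self) -> list[FoldSelection]:
        return [f.selection for f in self.folds if f.selection is not None]


def nested_cv(matrix: DesignMatrix, labels, protocol: CVProtocol,
              estimator: str = "lr", selection_mode: str = "none"
              ) -> EvaluationReport:
    """Run the nested cross-validation protocol on a design matrix.

    With ``selection_mode='lasso'`` the concept columns are filtered per
    outer fold by :func:`kgemr.select.lasso_select` on the training rows
    before the estimator search and fit; word columns always stay.
    """
    y = np.asarray(labels, dtype=int)
    X = sp.csr_matrix(matrix.X)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary with both classes present")
    if counts.min() < protocol.K:
        raise ValueError(f"K={protocol.K} exceeds the minority class count "
                         f"({counts.min()})")
    concept_mask = matrix.concept_mask()
    col_names = np.asarray(matrix.col_names, dtype=object)

    outer = StratifiedKFold(n_splits=protocol.K, shuffle=True,
                            random_state=protocol.seed)
    report = EvaluationReport(variant="", estimator=estimator)
    for k, (tr, te) in enumerate(outer.split(X, y), start=1):
        fold_seed = protocol.seed + 1000 * k
        rng = np.random.default_rng(fold_seed)
        X_tr, y_tr = X[tr], y[tr]
        X_te, y_te = X[te], y[te]

        selection = None
        col_idx = np.arange(X.shape[1])
        if selection_mode == "lasso" and concept_mask.any():
            selection = lasso_select(
                X_tr, y_tr, concept_mask,
                inner_folds=protocol.inner_selection_folds or protocol.L,
                seed=fold_seed, outer_fold_index=k,
                col_names=list(col_names))
            keep = ~concept_mask | np.isin(col_names,
                                           list(selection.selected_concepts))
            col_idx = np.where(keep)[0]
            X_tr = sp.csr_matrix(X_tr[:, col_idx])
            X_te = sp.csr_matrix(X_te[:, col_idx])
        elif selection_mode not in ("none", "lasso"):
            raise ValueError(f"unknown selection mode {selection_mode!r}")

        inner = StratifiedKFold(n_splits=protocol.L, shuffle=True,
                                random_state=fold_seed)
        inner_splits = list(inner.split(X_tr, y_tr))
        best_params, best_score = None, -np.inf
        for _ in range(protocol.n_iter):
            params = _sample_params(estimator, rng)
            scores = []
            for itr, ite in inner_splits:
                model = _build_estimator(estimator, params, fold_seed)
                model.fit(X_tr[itr], y_tr[itr])
                scores.append(f1_score(y_tr[ite], model.predict(X_tr[ite]),
                                       zero_division=0))
            score = float(np.mean(scores))
            if score > best_score:  # first-best tie-break
                best_score, best_params = score, params

        model = _build_estimator(estimator, best_params, fold_seed)
        model.fit(X_tr, y_tr)
        pred = model.predict(X_te)
        tp = int(((pred == 1) & (y_te == 1)).sum())
        fp = int(((pred == 1) & (y_te == 0)).sum())
        fn = int(((pred == 0) & (y_te == 1)).sum())
        tn = int(((pred == 0) & (y_te == 0)).sum())
        report.folds.append(FoldResult(
            fold_index=k, tp=tp, fp=fp, fn=fn, tn=tn,
            precision=precision_score(y_te, pred, zero_division=0),
            recall=recall_score(y_te, pred, zero_division=0),
            f1=f1_score(y_te, pred, zero_division=0),
            auc=float(roc_auc_score(y_te, _scores(model, X_te))),
            best_params=best_params, selection=selection))
    return report


def compare_variants(reports: dict[str, EvaluationReport],
                     baseline: str = "baseline", metric: str = "f1",
                     n_train: int | None = None, n_test: int = 1
                     ) -> list[dict]:
    """Corrected dependent t-test of every variant against the baseline on
    per-fold metric vectors (all reports must share the outer split).

    Identical per-fold vectors have zero difference variance; they are
    reported with ``identical=True`` instead of a t statistic.
    """
    base = reports[baseline]
    K = len(base.folds)
    if n_train is None:
        n_train = K - n_test
    rows = []
    for name, rep in reports.items():
        if name == baseline:
            continue
        if len(rep.folds) != K:
            raise ValueError(f"variant {name} has {len(rep.folds)} folds, "
                             f"baseline has {K}")
        A = rep.per_fold(metric)
        B = base.per_fold(metric)
        try:
            t, p = corrected_ttest(A, B, n_train=n_train, n_test=n_test)
            rows.append({"variant": name, "t": t, "p": p,
                         "identical": False})
        except ZeroDivisionError:
            rows.append({"variant": name, "t": None, "p": None,
                         "identical": True})
    return rows
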