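"""Evaluation statistics.

Contains the pooled cross-validation F-score, per-fold metric averaging,
the variance-corrected dependent t-test for cross-validated comparisons,
nominal-level Krippendorff's alpha for inter-annotator agreement, the
centered-cosine correlation distance, and the two risk-display formulas
(absolute risk reduction in percentage points, relative risk gain as a
rounded percentage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FoldCounts",
    "f_tp_fp",
    "avg_metrics",
    "corrected_ttest",
    "krippendorff_alpha",
    "correlation_distance",
    "absolute_risk_reduction",
    "relative_risk_gain",
]


@dataclass
class FoldCounts:
    """Per-outer-fold confusion counts."""

    tp: list[int]
    fp: list[int]
    fn: list[int]
    tn: list[int]

    def pooled(self) -> tuple[int, int, int, int]:
        return (int(sum(self.tp)), int(sum(self.fp)),
                int(sum(self.fn)), int(sum(self.tn)))


def f_tp_fp(counts: FoldCounts) -> float:
    """Pooled F-score over all folds: 2·TP_f / (2·TP_f + FP_f + FN_f),
    with TP_f, FP_f, FN_f summed across folds.  Equals the ordinary F1 when
    there is a single fold."""
    tp_f, fp_f, fn_f, _ = counts.pooled()
    denom = 2 * tp_f + fp_f + fn_f
    if denom == 0:
        raise ZeroDivisionError("pooled F-score undefined: no positive "
                                "predictions or instances")
    return 2.0 * tp_f / denom


def avg_metrics(per_fold: dict[str, list[float]]
                ) -> dict[str, tuple[float, float]]:
    """Arithmetic mean and sample standard deviation (ddof=1) per metric."""
    out = {}
    for name, values in per_fold.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need at least two folds to average")
        out[name] = (float(v.mean()), float(v.std(ddof=1)))
    return out


def corrected_ttest(A, B, n_train: int, n_test: int
                    ) -> tuple[float, float]:
    """Variance-corrected dependent t-test for per-fold metric differences.

    With x_j = A_j - B_j over n folds, the statistic is
    t = mean(x) / sqrt((1/n + n_test/n_train) * s²), where s² is the sample
    variance of x; the correction term n_test/n_train inflates the variance
    to account for the overlap of cross-validation training sets.  Returns
    (t, two-sided p) with n-1 degrees of freedom.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 1:
        raise ValueError("A and B must be equal-length vectors")
    x = A - B
    n = x.size
    if n < 2:
        raise ValueError("need at least two folds")
    var = float(x.var(ddof=1))
    if var == 0.0:
        raise ZeroDivisionError("zero variance of fold differences; "
                                "the corrected t statistic is undefined")
    t = float(x.mean() / np.sqrt((1.0 / n + n_test / n_train) * var))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def krippendorff_alpha(cells, level: str = "nominal") -> float:
    """Krippendorff's alpha from an annotators x units label matrix.

    *cells* is a 2-D array of hashable labels with ``None`` (or NaN) for
    missing entries.  Only the nominal level is implemented; units with
    fewer than two non-missing labels are excluded, per the standard
    coincidence-matrix construction.
    """
    if level != "nominal":
        raise NotImplementedError("only nominal-level alpha is implemented")
    cells = np.asarray(cells, dtype=object)
    if cells.ndim != 2 or cells.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two annotators")

    def missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    # Coincidence counts o[c][k]: each pairable unit of m values contributes
    # every ordered pair of values from distinct annotators with weight
    # 1/(m-1).
    from collections import Counter
    o: Counter = Counter()
    values_seen = set()
    any_pairable = False
    for u in range(cells.shape[1]):
        vals = [v for v in cells[:, u] if not missing(v)]
        m = len(vals)
        if m < 2:
            continue
        any_pairable = True
        for i, vi in enumerate(vals):
            values_seen.add(vi)
            for j, vj in enumerate(vals):
                if i != j:
                    o[(vi, vj)] += 1.0 / (m - 1)
    if not any_pairable:
        raise ValueError("no unit has two or more non-missing labels")

    cats = sorted(values_seen, key=str)
    n_c = {c: sum(o[(c, k)] for k in cats) for c in cats}
    n_total = sum(n_c.values())
    d_o = sum(o[(c, k)] for c in cats for k in cats if c != k)
    d_e = sum(n_c[c] * n_c[k] for c in cats for k in cats
              if c != k) / (n_total - 1)
    if d_e == 0.0:
        # a single category everywhere: perfect (if trivial) agreement
        return 1.0
    return 1.0 - d_o / d_e


def correlation_distance(u, v) -> float:
    """1 minus the centered cosine of two vectors; ranges over [0, 2].
    Raises on constant input (zero centered norm)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be equal-length vectors")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise ZeroDivisionError("correlation distance undefined for a "
                                "constant vector")
    return float(1.0 - (uc @ vc) / (nu * nv))


def absolute_risk_reduction(p0: float, p1: float) -> float:
    """Decrease of the hospitalization risk in percentage points when the
    selected risk factors are treated (risk p0% untreated, p1% treated)."""
    if not (0.0 <= p1 <= p0 <= 100.0):
        raise ValueError("require 0 <= p1 <= p0 <= 100")
    return p0 - p1


def relative_risk_gain(p0: float, p1: float) -> int:
    """Relative decrease of the hospitalization risk, rounded to the nearest
    integer percent: round(100·(p0 - p1)/p0)."""
    if p0 <= 0.0:
        raise ValueError("baseline risk must be positive")
    if not 0.0 <= p1 <= p0:
        raise ValueError("require 0 <= p1 <= p0")
    return int(round(100.0 * (p0 - p1) / p0))
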