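"""Truth-aware scoring of per-gene test results.

Given a result table and the ground-truth DE status, this module computes
confusion counts at a significance threshold, ROC curves (TPR vs FPR over
thresholds), empirical type-I error curves over a grid of nominal levels,
uniform Q-Q data for null genes, p-value histograms, and pointwise
aggregation of curves across datasets.  No multiple-testing correction is
applied anywhere: the object of study is the raw behavior of nominal
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ResultTable, TruthTable

__all__ = [
    "ConfusionCounts",
    "EvalCurve",
    "QQData",
    "confusion_at",
    "roc_curve",
    "type1_curve",
    "qq_uniform",
    "pvalue_histogram",
    "aggregate",
    "auc",
]

#: Default grid of nominal significance levels, log-spaced over the region
#: where miscalibration of count tests is most visible.
DEFAULT_NOMINAL_GRID = np.logspace(-4, -1, 30)


@dataclass
class ConfusionCounts:
    """Declared-vs-true classification counts at one threshold."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for v in (self.TP, self.FP, self.TN, self.FN):
            if v < 0:
                raise ValueError("confusion counts must be nonnegative")

    @property
    def S0_count(self) -> int:
        return self.FP + self.TN

    @property
    def S1_count(self) -> int:
        return self.TP + self.FN

    @property
    def R0(self) -> int:
        return self.TN + self.FN

    @property
    def R1(self) -> int:
        return self.FP + self.TP

    @property
    def G_total(self) -> int:
        return self.S0_count + self.S1_count

    @property
    def TPR(self) -> float:
        return self.TP / self.S1_count if self.S1_count else float("nan")

    @property
    def FPR(self) -> float:
        return self.FP / self.S0_count if self.S0_count else float("nan")


@dataclass
class EvalCurve:
    """Thresholds with TPR, FPR and empirical type-I error."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    type1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "TPR": self.tpr,
                "FPR": self.fpr,
                "type1": self.type1,
            }
        )


@dataclass
class QQData:
    """Uniform Q-Q data for null-gene p-values, on the -log10 scale."""

    expected: np.ndarray
    observed: np.ndarray
    zero_replacement: float | None

    def __post_init__(self) -> None:
        if self.expected.size != self.observed.size:
            raise ValueError("expected and observed lengths differ")


def _align(results: ResultTable, truth: TruthTable):
    """Match results to truth by gene id, dropping missing-p genes."""
    tr = {g: i for i, g in enumerate(truth.gene_ids)}
    missing = [g for g in results.gene_ids if g not in tr]
    if missing:
        raise ValueError(f"genes absent from truth table: {missing[:5]}")
    idx = np.array([tr[g] for g in results.gene_ids])
    p = results.p_value
    ok = ~np.isnan(p)
    return p[ok], truth.is_de[idx][ok], int((~ok).sum())


def confusion_at(
    results: ResultTable, truth: TruthTable, alpha: float
) -> ConfusionCounts:
    """Confusion counts with the inclusive declaration rule ``p <= alpha``."""
    p, is_de, _ = _align(results, truth)
    declared = p <= alpha
    return ConfusionCounts(
        TP=int((declared & is_de).sum()),
        FP=int((declared & ~is_de).sum()),
        TN=int((~declared & ~is_de).sum()),
        FN=int((~declared & is_de).sum()),
    )


def _rates_at(p, is_de, thresholds):
    """Vectorized TPR/FPR at many thresholds via sorted p-values."""
    s1 = np.sort(p[is_de])
    s0 = np.sort(p[~is_de])
    n1, n0 = s1.size, s0.size
    tp = np.searchsorted(s1, thresholds, side="right")
    fp = np.searchsorted(s0, thresholds, side="right")
    tpr = tp / n1 if n1 else np.full(len(thresholds), np.nan)
    fpr = fp / n0 if n0 else np.full(len(thresholds), np.nan)
    return tpr, fpr


def roc_curve(
    results: ResultTable,
    truth: TruthTable,
    thresholds: np.ndarray | None = None,
) -> EvalCurve:
    """ROC sweep over thresholds (default: all distinct p-values plus 0, 1).

    The curve is a step function starting at (0, 0) and ending at (1, 1);
    empirical type-I error equals FPR (it is computed on S0 genes only).
    """
    p, is_de, _ = _align(results, truth)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0, 1.0], p]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    tpr, fpr = _rates_at(p, is_de, thresholds)
    return EvalCurve(thresholds, tpr, fpr, fpr.copy())


def type1_curve(
    results: ResultTable,
    truth: TruthTable,
    nominal: np.ndarray | None = None,
) -> EvalCurve:
    """Empirical type-I error (FPR over S0 genes) at nominal levels."""
    nominal = DEFAULT_NOMINAL_GRID if nominal is None else np.asarray(nominal)
    p, is_de, _ = _align(results, truth)
    tpr, fpr = _rates_at(p, is_de, np.sort(nominal))
    return EvalCurve(np.sort(nominal), tpr, fpr, fpr.copy())


def qq_uniform(results: ResultTable, truth: TruthTable) -> QQData:
    """Uniform Q-Q data for the S0 genes' p-values.

    Zero p-values (possible with engine-agnostic input, e.g. permutation
    procedures without an add-one rule) are replaced by the minimum positive
    observed p-value before taking logs; both axes are -log10 scaled with
    expected quantiles i/(m+1).
    """
    p, is_de, _ = _align(results, truth)
    p0 = p[~is_de]
    if p0.size == 0:
        raise ValueError("no null (S0) genes with observed p-values")
    zero_repl = None
    if (p0 == 0).any():
        positive = p0[p0 > 0]
        if positive.size == 0:
            raise ValueError("all null p-values are zero; no replacement exists")
        zero_repl = float(positive.min())
        p0 = np.where(p0 == 0, zero_repl, p0)
    m = p0.size
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    observed = -np.log10(np.sort(p0))[::-1]
    # both sequences sorted ascending for plotting convenience
    return QQData(np.sort(expected), np.sort(observed), zero_repl)


def pvalue_histogram(
    results: ResultTable, truth: TruthTable, bins: int = 20
) -> np.ndarray:
    """Counts of S0-gene p-values in equal-width bins over [0, 1]."""
    p, is_de, _ = _align(results, truth)
    counts, _ = np.histogram(p[~is_de], bins=bins, range=(0.0, 1.0))
    return counts


def auc(curve: EvalCurve) -> float:
    """Area under the ROC curve by trapezoidal rule over (FPR, TPR)."""
    order = np.argsort(curve.fpr)
    return float(np.trapezoid(curve.tpr[order], curve.fpr[order]))


def aggregate(curves: list[EvalCurve]) -> tuple[list[EvalCurve], EvalCurve]:
    """Per-dataset curves plus their pointwise mean on a common grid.

    Every individual curve is retained — the spread across datasets is
    itself a finding — and a mean curve is formed by linear interpolation of
    each curve onto the union of all thresholds.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    grid = np.unique(np.concatenate([c.thresholds for c in curves]))

    def interp(c: EvalCurve, y: np.ndarray) -> np.ndarray:
        return np.interp(grid, c.thresholds, y)

    tpr = np.mean([interp(c, c.tpr) for c in curves], axis=0)
    fpr = np.mean([interp(c, c.fpr) for c in curves], axis=0)
    t1 = np.mean([interp(c, c.type1) for c in curves], axis=0)
    return curves, EvalCurve(grid, tpr, fpr, t1)
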