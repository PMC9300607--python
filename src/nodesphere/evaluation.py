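"""Diagnostic-accuracy evaluation.

Confusion-count arithmetic (sensitivity, specificity, accuracy — the
correct classification rate at patient level), empirical ROC curves and
trapezoid AUC, and the four-fold (2x2) Pearson chi-square used to
compare two methods' correct/incorrect counts.

Conventions:

* higher score = metastatic for both shape formulas (metastatic nodes
  are rounder); automatic score orientation is available but off by
  default and logged loudly when it flips;
* chi-square is computed without Yates continuity correction by
  default — the study's printed p-values match the uncorrected
  statistic — with the correction available behind a flag;
* a metric whose denominator is empty is flagged as undefined (None),
  never silently propagated as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN of a binary diagnostic call against pathology."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def errors(self) -> int:
        return self.fp + self.fn

    @classmethod
    def from_calls(
        cls, calls: Sequence[int], truth: Sequence[int]
    ) -> "ConfusionCounts":
        c = np.asarray(calls, dtype=int)
        t = np.asarray(truth, dtype=int)
        if c.shape != t.shape:
            raise ValueError("calls and truth must align")
        return cls(
            tp=int(((c == 1) & (t == 1)).sum()),
            fp=int(((c == 1) & (t == 0)).sum()),
            tn=int(((c == 0) & (t == 0)).sum()),
            fn=int(((c == 0) & (t == 1)).sum()),
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Rates in [0, 1]; None marks a rate whose denominator is empty.

    ``correct_classification_rate`` is the accuracy synonym used when
    calls are at patient level; ``unit`` records whether the counts were
    per node or per patient, so rates at different units are never mixed.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    youden_j: Optional[float]
    unit: str = "node"

    @property
    def correct_classification_rate(self) -> float:
        return self.accuracy


def confusion_metrics(counts: ConfusionCounts, unit: str = "node") -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy (CCR) from a confusion table."""
    n = counts.total
    if n == 0:
        raise ValueError("all-zero confusion counts: nothing was evaluated")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sens = counts.tp / pos if pos > 0 else None
    spec = counts.tn / neg if neg > 0 else None
    youden = sens + spec - 1.0 if (sens is not None and spec is not None) else None
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=(counts.tp + counts.tn) / n,
        youden_j=youden,
        unit=unit,
    )


@dataclass
class ROCResult:
    """Empirical ROC curve and trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    flipped: bool = False


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    auto_orient: bool = False,
) -> ROCResult:
    """Empirical ROC over all distinct thresholds, AUC by trapezoid.

    The positive direction is fixed as "higher score = metastatic". With
    ``auto_orient`` the score sign is flipped when AUC < 0.5 — logged
    loudly, since a flipped orientation usually signals an upstream
    mistake.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if y.min() == y.max():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    area = float(_sk_auc(fpr, tpr))
    flipped = False
    if auto_orient and area < 0.5:
        logger.warning(
            "AUC %.3f < 0.5: flipping score orientation (auto_orient)", area
        )
        fpr, tpr, thr = _sk_roc_curve(y, -s)
        area = float(_sk_auc(fpr, tpr))
        flipped = True
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=area, flipped=flipped)


def chi2_fourfold(
    correct_a: int,
    wrong_a: int,
    correct_b: int,
    wrong_b: int,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 method-comparison table.

    Rows are methods, columns correct/incorrect counts. Closed form
    chi2 = N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with 1 df; Yates
    continuity correction optional (off by default).
    """
    a, b, c, d = correct_a, wrong_a, correct_b, wrong_b
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a table margin is zero")
    det = a * d - b * c
    if correction:
        det = max(abs(det) - n / 2.0, 0.0)
    stat = n * float(det) ** 2 / float(np.prod(margins, dtype=float))
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def evaluate_method(
    calls: pd.DataFrame,
    unit: str = "patient",
    subgroup: Optional[str] = None,
) -> tuple[DiagnosticMetrics, ConfusionCounts]:
    """Metrics for one method's calls against truth, optionally on a subgroup.

    ``calls`` needs columns ``call`` and ``truth`` (binary); an optional
    boolean/0-1 column named by ``subgroup`` (e.g. "nac") restricts the
    evaluation to the flagged rows.
    """
    for col in ("call", "truth"):
        if col not in calls.columns:
            raise ValueError(f"calls table lacks column {col!r}")
    frame = calls
    if subgroup is not None:
        if subgroup not in frame.columns:
            raise ValueError(f"no subgroup column {subgroup!r}")
        frame = frame[frame[subgroup].astype(bool)]
    if frame.empty:
        raise ValueError("no rows to evaluate (empty cohort or subgroup)")
    counts = ConfusionCounts.from_calls(
        frame["call"].to_numpy(), frame["truth"].to_numpy()
    )
    return confusion_metrics(counts, unit=unit), counts


def plot_roc(roc: ROCResult, path: str, title: str = "ROC") -> None:
    """Write a simple ROC plot to ``path`` (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post",
            label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
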