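"""Evaluation metrics and the statistical tests used by the cost comparison.

AUC is one-vs-rest: binary tasks use the standard trapezoidal/midrank ROC AUC
of the positive-class score; multiclass tasks average the per-class one-vs-rest
AUCs over classes actually present in the evaluation set (unweighted, i.e.
macro).  Precision/recall/F1 come in macro (unweighted class mean) and
weighted (support-weighted) flavours; for single-label classification the
weighted recall is algebraically the accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

__all__ = [
    "MetricSet",
    "auc_ovr_macro",
    "classification_metrics",
    "marker_expression_test",
    "panel_size_test",
]


@dataclass(frozen=True)
class MetricSet:
    auc: float | None
    accuracy: float
    macro_f1: float
    macro_precision: float
    macro_recall: float
    weighted_f1: float
    weighted_precision: float
    weighted_recall: float

    def to_dict(self) -> dict:
        return asdict(self)


def auc_ovr_macro(scores: np.ndarray, labels: Sequence[str],
                  class_labels: Sequence[str]) -> float:
    """Macro one-vs-rest ROC AUC.

    Parameters
    ----------
    scores
        ``(n_cases, n_classes)`` score matrix whose columns align with
        ``class_labels``.  Scores need only be rank-valid (decision values
        are fine); ties are handled by the midrank convention.
    labels
        True class label per case.
    class_labels
        Column order of ``scores``.

    Classes absent from ``labels`` are skipped (one-vs-rest AUC is undefined
    without positives); a warning notes each skip.  With exactly two classes
    this reduces to the ordinary ROC AUC of the second (positive) column.
    """
    labels = np.asarray(labels, dtype=object)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape != (len(labels), len(class_labels)):
        raise ValueError("scores shape must be (n_cases, n_classes)")
    present = [c for c in class_labels if np.any(labels == c)]
    if len(present) < 2:
        raise ValueError("need at least 2 distinct labels for AUC")
    if len(class_labels) == 2:
        y = (labels == class_labels[1]).astype(int)
        return float(roc_auc_score(y, scores[:, 1]))
    aucs = []
    for c in present:
        j = list(class_labels).index(c)
        y = (labels == c).astype(int)
        aucs.append(roc_auc_score(y, scores[:, j]))
    skipped = set(class_labels) - set(present)
    if skipped:
        warnings.warn(f"classes absent from evaluation set skipped in macro "
                      f"AUC: {sorted(skipped)}", stacklevel=2)
    return float(np.mean(aucs))


def classification_metrics(predicted: Sequence[str], true: Sequence[str],
                           class_labels: Sequence[str] | None = None,
                           auc: float | None = None) -> MetricSet:
    """Accuracy plus macro/weighted precision, recall and F1.

    Per-class ratios with a 0/0 numerator are defined as 0.  ``class_labels``
    fixes the class universe for macro averaging; by default the classes
    observed in ``true`` are used.
    """
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if len(predicted) != len(true):
        raise ValueError("label vectors must have the same length")
    if len(true) == 0:
        raise ValueError("empty input")
    labels = (list(class_labels) if class_labels is not None
              else sorted(set(true)))
    accuracy = float(np.mean(predicted == true))
    macro_p, macro_r, macro_f1, _ = precision_recall_fscore_support(
        true, predicted, labels=labels, average="macro", zero_division=0)
    w_p, w_r, w_f1, _ = precision_recall_fscore_support(
        true, predicted, labels=labels, average="weighted", zero_division=0)
    return MetricSet(
        auc=auc,
        accuracy=accuracy,
        macro_f1=float(macro_f1),
        macro_precision=float(macro_p),
        macro_recall=float(macro_r),
        weighted_f1=float(w_f1),
        weighted_precision=float(w_p),
        weighted_recall=float(w_r),
    )


def marker_expression_test(table: np.ndarray | Sequence[Sequence[float]]
                           ) -> tuple[float, float]:
    """Pearson chi-square test of independence on a subtype x status table.

    No continuity correction; the p-value uses (r-1)(c-1) degrees of freedom.
    Zero row or column margins are an error.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue)


def panel_size_test(required: Sequence[float], clinical: Sequence[float],
                    method: str = "auto") -> float:
    """Two-sided comparison of marker counts (Welch t or Mann-Whitney U).

    ``method="auto"`` uses Welch's t-test only when both samples pass a
    Shapiro normality screen at alpha = 0.05, and otherwise the Mann-Whitney
    U test (normal approximation with tie correction).  Two identical
    constant samples return p = 1 by convention.
    """
    a = np.asarray(required, dtype=float)
    b = np.asarray(clinical, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method not in ("auto", "t", "mannwhitney"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "t" if _both_normal(a, b) else "mannwhitney"
    if method == "t":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tie samples warn, p handled above
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    return float(res.pvalue)


def _both_normal(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> bool:
    for x in (a, b):
        if x.size < 3 or np.all(x == x[0]):
            return False
        sample = x if x.size <= 5000 else x[:5000]  # shapiro's supported range
        if stats.shapiro(sample).pvalue <= alpha:
            return False
    return True
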