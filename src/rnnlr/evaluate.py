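"""One-against-all evaluation: confusion matrices, P/R/F, AUC, curves,
and repeated-trial significance testing.

For a K-class problem each class is scored one-against-all: the other
classes are pooled as the negative class and binary precision, recall,
F-measure and ROC AUC are computed, using the positive class's predicted
probability as the ranking score for AUC.  Rendered reports round half-up
to 2 decimals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .schema import CLASS_ORDER

__all__ = [
    "ConfusionMatrix", "EvaluationReport", "confusion", "one_vs_all_metrics",
    "roc_auc_ova", "pr_curve", "repeated_trials", "paired_t",
    "evaluation_report", "worked_example_confusion", "round2",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matches printed clinical tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"actual_{c}" for c in self.class_order],
                            columns=[f"pred_{c}" for c in self.class_order])


def confusion(actual: np.ndarray, predicted: np.ndarray,
              class_order: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    """Exact count matrix; labels may be class codes or class names."""
    k = len(class_order)

    def codes(arr):
        arr = np.asarray(arr)
        if arr.dtype.kind in "iu":
            if arr.size and (arr.min() < 0 or arr.max() >= k):
                raise ValueError("class code outside class_order")
            return arr.astype(int)
        lut = {c: i for i, c in enumerate(class_order)}
        try:
            return np.array([lut[v] for v in arr], dtype=int)
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None

    a, p = codes(actual), codes(predicted)
    if len(a) != len(p):
        raise ValueError("actual and predicted must have equal length")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (a, p), 1)
    return ConfusionMatrix(counts, class_order)


def one_vs_all_metrics(cm: ConfusionMatrix,
                       positive: int | str) -> tuple[float, float, float]:
    """(precision, recall, F) for one positive class pooled against the rest.

    0/0 quotients are reported as 0 with a warning (no positive predictions
    or no positive instances).
    """
    k = positive if isinstance(positive, int) else cm.class_order.index(positive)
    tp = cm.counts[k, k]
    fn = cm.counts[k].sum() - tp
    fp = cm.counts[:, k].sum() - tp

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f = 0.0 if precision + recall == 0 else \
        2 * precision * recall / (precision + recall)
    return precision, recall, f


def roc_auc_ova(actual: np.ndarray, probabilities: np.ndarray,
                positive: int | str,
                class_order: tuple[str, ...] = CLASS_ORDER) -> float:
    """One-vs-rest ROC AUC with the positive-class probability as score.

    Equals the normalised Mann-Whitney U statistic (ties count one half).
    """
    k = positive if isinstance(positive, int) else class_order.index(positive)
    y = (np.asarray(actual) == k).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(y, np.asarray(probabilities)[:, k]))


def pr_curve(actual: np.ndarray, probabilities: np.ndarray,
             positive: int | str,
             class_order: tuple[str, ...] = CLASS_ORDER) -> list[tuple[float, float]]:
    """(recall, precision) pairs across unique score thresholds.

    Includes the all-positive endpoint (recall 1, precision = prevalence)
    and the (0, 1) endpoint; recall is monotone along the returned list.
    """
    k = positive if isinstance(positive, int) else class_order.index(positive)
    y = (np.asarray(actual) == k).astype(int)
    if y.min() == y.max():
        raise ValueError("PR curve needs at least one positive and one negative")
    precision, recall, _ = precision_recall_curve(y, np.asarray(probabilities)[:, k])
    return sorted(zip(recall.tolist(), precision.tolist()))


@dataclass
class EvaluationReport:
    """Per-class one-against-all metrics plus the full confusion matrix."""

    cm: ConfusionMatrix
    per_class: pd.DataFrame  # columns precision/recall/f_measure/auc
    extras: dict = field(default_factory=dict)

    def rendered(self) -> pd.DataFrame:
        """2-decimal (half-up) table as printed in clinical reports."""
        return self.per_class.map(
            lambda v: round2(v) if pd.notna(v) else v)

    def to_json(self) -> str:
        return json.dumps({
            "confusion": self.cm.counts.tolist(),
            "class_order": list(self.cm.class_order),
            "per_class": self.per_class.to_dict(orient="index"),
            **self.extras,
        }, indent=2)


def evaluation_report(actual: np.ndarray, predicted: np.ndarray,
                      probabilities: np.ndarray | None = None,
                      class_order: tuple[str, ...] = CLASS_ORDER) -> EvaluationReport:
    """Full one-against-all report; AUC columns require probabilities."""
    cm = confusion(actual, predicted, class_order)
    rows = {}
    for i, label in enumerate(class_order):
        p, r, f = one_vs_all_metrics(cm, i)
        auc = np.nan
        if probabilities is not None:
            y = np.asarray(actual)
            y = y if y.dtype.kind in "iu" else np.array(
                [class_order.index(v) for v in y])
            if 0 < (y == i).sum() < len(y):
                auc = roc_auc_ova(y, probabilities, i, class_order)
        rows[label] = {"precision": p, "recall": r, "f_measure": f, "auc": auc}
    return EvaluationReport(cm, pd.DataFrame.from_dict(rows, orient="index"))


def worked_example_confusion() -> ConfusionMatrix:
    """The bundled held-out confusion matrix of the published predictor."""
    with resources.files("rnnlr.data").joinpath("worked_confusion.json").open() as fh:
        payload = json.load(fh)
    return ConfusionMatrix(np.asarray(payload["matrix"]),
                           tuple(payload["class_order"]))


# ---------------------------------------------------------------------------
# Repeated trials
# ---------------------------------------------------------------------------

def repeated_trials(pipeline, seeds) -> pd.DataFrame:
    """Run ``pipeline(seed) -> dict of metrics`` once per seed.

    Trials differ only by seed; the result is a tidy per-trial metric table
    suitable for seed-matched paired testing between methods.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least 2 trials")
    rows = []
    for s in seeds:
        row = {"seed": s}
        row.update(pipeline(s))
        rows.append(row)
    return pd.DataFrame(rows)


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on seed-matched differences.

    Zero-variance differences are an exact tie: p = 1.0 when the mean
    difference is 0 (with a warning), else p = 0.0 (a constant nonzero
    shift is unambiguous).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        warnings.warn("zero-variance differences; exact-tie convention",
                      stacklevel=2)
        return (0.0, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
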