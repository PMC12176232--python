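"""Confusion matrices and the four headline metrics, as percentages.

accuracy    = 100 (TN + TP) / total
recall      = 100 TP / (TP + FN)        (sensitivity)
specificity = 100 TN / (TN + FP)
precision   = 100 TP / (TP + FP)
F1          = 2 * precision * recall / (precision + recall)

Any metric whose denominator is zero is 0 by convention — so a model that
never predicts the positive class has F1 = 0 and specificity = 100, which is
exactly how the reference tables this package reproduces print such rows.
``table_check`` recomputes metrics from a confusion matrix and flags each
printed value as consistent or not, at the value's own printed precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_FLOOR, ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .features import FeatureMatrix
from .models import TrainedModel, predict

METRICS = ("accuracy", "recall", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TN/FP/FN/TP counts of one binary evaluation."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        counts = (self.tn, self.fp, self.fn, self.tp)
        if any(c < 0 or c != int(c) for c in counts):
            raise ValueError("confusion-matrix counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def scaled(self, factor: int) -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tn * factor, self.fp * factor, self.fn * factor, self.tp * factor
        )

    def to_dict(self) -> dict:
        return {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp}


@dataclass(frozen=True)
class MetricsReport:
    """The four metrics (plus precision) recomputable from the embedded counts."""

    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    cm: ConfusionMatrix
    rounding: int = 1

    def to_dict(self) -> dict:
        return {
            "metrics": {m: getattr(self, m) for m in METRICS},
            "cm": self.cm.to_dict(),
            "rounding": self.rounding,
        }

    def rounded(self) -> dict:
        return {m: round_half_even(getattr(self, m), self.rounding) for m in METRICS}


def round_half_even(x: float, decimals: int = 1) -> float:
    """Display rounding, half to even (2.25 -> 2.2, 2.35 -> 2.4)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def _truncate(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_FLOOR))


def confusion_counts(y_true, y_pred) -> ConfusionMatrix:
    """Tally TN/FP/FN/TP from two equal-length binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(y, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    tn, fp, fn, tp = _sk_confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionMatrix(int(tn), int(fp), int(fn), int(tp))


def metrics_from_counts(cm: ConfusionMatrix, rounding: int = 1) -> MetricsReport:
    """All metrics from one confusion matrix; zero denominators give 0."""

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den else 0.0

    accuracy = ratio(cm.tn + cm.tp, cm.total)
    recall = ratio(cm.tp, cm.tp + cm.fn)
    specificity = ratio(cm.tn, cm.tn + cm.fp)
    precision = ratio(cm.tp, cm.tp + cm.fp)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(accuracy, recall, specificity, precision, f1, cm, rounding)


def evaluate_model(
    model: TrainedModel, fm: FeatureMatrix, extra: dict | None = None
) -> tuple[MetricsReport, dict]:
    """Predict, tally and report; the report JSON carries config and digests."""
    if fm.labels is None:
        raise ValueError("evaluation requires labels")
    table = predict(model, fm)
    cm = confusion_counts(fm.labels, table["label"].to_numpy())
    report = metrics_from_counts(cm)
    digest = hashlib.sha256(
        fm.values.tobytes() + json.dumps(fm.ids).encode()
    ).hexdigest()
    payload = {
        **report.to_dict(),
        "config": model.config.to_dict(),
        "seed": model.config.seed,
        "n_eval_rows": int(fm.n),
        "data_sha256": digest,
    }
    if extra:
        payload.update(extra)
    return report, payload


def table_check(cm: ConfusionMatrix, printed: dict) -> dict:
    """Compare recomputed metrics against printed values or [lo, hi] ranges.

    A point value is consistent when the recomputed metric, rounded (half to
    even) or truncated to the value's printed precision, equals it — the
    reference tables mix both display conventions.  A range is consistent
    when the recomputed metric lies within [lo, hi] with half-a-last-digit
    slack.  Returns per-metric ``{recomputed, printed, consistent}``.
    """
    report = metrics_from_counts(cm)
    out: dict[str, dict] = {}
    for metric, value in printed.items():
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        recomputed = getattr(report, metric)
        if isinstance(value, (tuple, list)):
            lo, hi = float(value[0]), float(value[1])
            consistent = (lo - 0.05) <= recomputed <= (hi + 0.05)
        else:
            decimals = _printed_decimals(value)
            consistent = float(value) in (
                round_half_even(recomputed, decimals),
                _truncate(recomputed, decimals),
            )
        out[metric] = {
            "recomputed": recomputed,
            "printed": value,
            "consistent": bool(consistent),
        }
    return out


def _printed_decimals(value: float) -> int:
    text = repr(float(value))
    if "." in text:
        frac = text.split(".")[1].rstrip("0")
        return max(len(frac), 0)
    return 0


def table_check_frame(results: dict[str, dict]) -> pd.DataFrame:
    """Flatten nested ``{row: table_check(...)}`` results for display."""
    rows = []
    for label, checks in results.items():
        for metric, entry in checks.items():
            rows.append({"row": label, "metric": metric, **entry})
    return pd.DataFrame(rows)
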