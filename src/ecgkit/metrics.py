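"""Evaluation metrics.

Signal fidelity between a clean reference y and an estimate y′:

* MSE  = Σ(yᵢ − yᵢ′)²/n
* MAE  = Σ|yᵢ − yᵢ′|/n
* R²   = 1 − SS_res/SS_tot, SS_tot taken about the mean of the reference
  (can be negative when the estimate is worse than the mean)
* Pearson r — centred cosine of the two vectors, in [−1, 1]

Classification quality for the five beat classes: confusion matrix in fixed
(N, L, R, A, V) order, per-class one-vs-rest precision/recall/F1, unweighted
macro averages, and accuracy = trace/total.  Macro averaging is used for the
headline numbers because it is the conservative choice under heavy class
imbalance; per-class values are always reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .synth import BEAT_CLASSES


@dataclass
class FidelityReport:
    mse: float
    mae: float
    r_squared: float
    pearson_r: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_fidelity(original: np.ndarray, estimate: np.ndarray) -> FidelityReport:
    """All four fidelity metrics of ``estimate`` against the clean ``original``."""
    y = np.asarray(original, dtype=float)
    yp = np.asarray(estimate, dtype=float)
    if y.shape != yp.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yp.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    resid = y - yp
    mse = float(np.mean(resid ** 2))
    mae = float(np.mean(np.abs(resid)))

    yc = y - y.mean()
    ss_tot = float(np.sum(yc ** 2))
    if ss_tot == 0.0:
        raise ValueError("original signal is constant; R² and r are undefined")
    r_squared = 1.0 - float(np.sum(resid ** 2)) / ss_tot

    ypc = yp - yp.mean()
    denom = np.sqrt(np.sum(yc ** 2) * np.sum(ypc ** 2))
    pearson = float(np.sum(yc * ypc) / denom) if denom > 0 else 0.0
    return FidelityReport(mse, mae, r_squared, min(1.0, max(-1.0, pearson)))


@dataclass
class ConfusionMatrix:
    """Square count table; cell (i, j) = items of true class i predicted as j."""

    counts: np.ndarray
    labels: tuple[str, ...] = BEAT_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the label set")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "counts": self.counts.tolist()}


def confusion_matrix(y_true, y_pred,
                     labels: tuple[str, ...] = BEAT_CLASSES) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} not in {labels}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


@dataclass
class ClassificationReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    cm: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                lab: {"precision": self.precision[lab],
                      "recall": self.recall[lab],
                      "f1": self.f1[lab]}
                for lab in self.cm.labels
            },
            "confusion_matrix": self.cm.to_dict(),
        }


def classification_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Per-class and macro precision/recall/F1 plus accuracy, from counts.

    A class with zero predicted (or zero true) positives gets precision
    (recall) 0 with a warning, so degenerate epochs do not abort a benchmark.
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    precision, recall, f1 = {}, {}, {}
    for i, lab in enumerate(cm.labels):
        tp = float(c[i, i])
        pred_pos = float(c[:, i].sum())
        true_pos = float(c[i, :].sum())
        if pred_pos == 0:
            warnings.warn(f"class {lab}: no predicted positives; precision set to 0")
        p = tp / pred_pos if pred_pos > 0 else 0.0
        r = tp / true_pos if true_pos > 0 else 0.0
        precision[lab] = p
        recall[lab] = r
        f1[lab] = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    k = len(cm.labels)
    return ClassificationReport(
        accuracy=float(np.trace(c)) / total,
        precision=precision, recall=recall, f1=f1,
        macro_precision=sum(precision.values()) / k,
        macro_recall=sum(recall.values()) / k,
        macro_f1=sum(f1.values()) / k,
        cm=cm,
    )


def fidelity_table(rows: dict[str, FidelityReport]) -> str:
    """Aligned text table: methods × {MSE, R², MAE, Correlation}."""
    header = f"{'Method':<14}{'MSE':>12}{'R^2':>12}{'MAE':>12}{'Correlation':>14}"
    lines = [header, "-" * len(header)]
    for name, r in rows.items():
        lines.append(f"{name:<14}{r.mse:>12.6f}{r.r_squared:>12.4f}"
                     f"{r.mae:>12.6f}{r.pearson_r:>14.4f}")
    return "\n".join(lines)


def report_to_json(obj, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(
        obj.to_dict() if hasattr(obj, "to_dict") else obj,
        indent=1, sort_keys=True))
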