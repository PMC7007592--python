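"""Blinded held-out evaluation, diagnostic metrics, and confidence cutoffs.

Metric conventions
------------------
All per-class metrics are one-vs-rest on the confusion matrix (rows = true
class, columns = predicted class):

    sensitivity (recall)  = TP / (TP + FN)
    specificity           = TN / (TN + FP)
    PPV (precision)       = TP / (TP + FP)
    NPV                   = TN / (TN + FN)
    F1                    = 2 * PPV * sensitivity / (PPV + sensitivity)

A ratio with a zero denominator is reported as NaN ("not computable"), never
silently as 0 — emitting 0 would misstate performance (e.g. NPV when nothing
was predicted negative).  AUROC is the rank statistic (ties get half
credit); for more than two classes it is one-vs-rest, macro-averaged.

Blinding
--------
A held-out test set is wrapped in a :class:`BlindedSet`: predictions can be
produced from it, but its labels are sealed and no metric can be computed
until an explicit, logged ``unblind()`` call.  Unblinding is idempotent and
logged exactly once.

Confidence cutoffs
------------------
Because the classifier reports a probability with every call, a user can
accept only predictions at or above a cutoff and route the rest to manual
chart review.  :func:`confidence_filter` applies one cutoff;
:func:`confidence_curve` tabulates yield and accuracy across all observed
confidence levels.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import PatientVector
from .models import Prediction, TrainedModel, predict

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "BlindedSet",
    "BlindingError",
    "confusion",
    "compute_metrics",
    "confidence_filter",
    "confidence_curve",
    "make_blinded",
    "evaluate_blinded",
    "write_report_json",
    "format_report_text",
    "export_reviewed_predictions",
]

logger = logging.getLogger(__name__)


class BlindingError(RuntimeError):
    """Labels of a blinded set were requested before unblinding."""


@dataclass(frozen=True)
class ConfusionMatrix:
    class_names: tuple[str, ...]
    counts: np.ndarray  # rows = true class, cols = predicted class

    def __post_init__(self) -> None:
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating ``cls`` as positive and the rest as negative."""
        i = self.class_names.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    per_class: Mapping[str, Mapping[str, float]]  # sensitivity/specificity/ppv/npv/f1
    auroc: float | None
    n_evaluated: int
    n_abstained: int = 0
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {c: dict(m) for c, m in self.per_class.items()},
            "auroc": self.auroc,
            "n_evaluated": self.n_evaluated,
            "n_abstained": self.n_abstained,
            "notes": list(self.notes),
        }


def confusion(
    true_labels: Mapping[str, str] | Sequence[str],
    predictions: Sequence[Prediction] | Sequence[str],
) -> ConfusionMatrix:
    """Tally a confusion matrix.

    Accepts either aligned label sequences or a patient->label map plus
    Prediction objects.  An unseen *predicted* label (one absent from the
    true-label set and the predictions' score keys) is an error.
    """
    if isinstance(true_labels, Mapping):
        preds: Sequence[Prediction] = predictions  # type: ignore[assignment]
        y_true = [true_labels[p.patient_id] for p in preds]
        y_pred = [p.predicted_label for p in preds]
        known = set(y_true) | set().union(*(p.class_scores.keys() for p in preds))
    else:
        y_true = list(true_labels)
        y_pred = [p.predicted_label if isinstance(p, Prediction) else p for p in predictions]
        known = set(y_true)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    stray = set(y_pred) - known
    if stray:
        raise ValueError(f"predicted labels never seen among true classes: {sorted(stray)}")
    classes = tuple(sorted(known))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes, counts)


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def compute_metrics(
    cm: ConfusionMatrix,
    y_true: Sequence[str] | None = None,
    scores: Sequence[Mapping[str, float]] | None = None,
    n_abstained: int = 0,
) -> MetricsReport:
    """Derive accuracy and one-vs-rest diagnostics from a confusion matrix.

    AUROC requires per-patient class scores aligned with ``y_true``; when
    scores are absent it is omitted (None), never guessed.
    """
    if cm.total < 1:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    accuracy = float(np.trace(cm.counts)) / cm.total

    per_class: dict[str, dict[str, float]] = {}
    notes: list[str] = []
    for cls in cm.class_names:
        tp, fp, fn, tn = cm.one_vs_rest(cls)
        m = {
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "ppv": _ratio(tp, tp + fp),
            "npv": _ratio(tn, tn + fn),
        }
        if math.isnan(m["ppv"]) or math.isnan(m["sensitivity"]) or (m["ppv"] + m["sensitivity"]) == 0:
            m["f1"] = math.nan
        else:
            m["f1"] = 2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"])
        for name, val in m.items():
            if math.isnan(val):
                notes.append(f"{cls}: {name} not computable (zero denominator)")
        per_class[cls] = m

    auroc: float | None = None
    if scores is not None:
        if y_true is None or len(y_true) != len(scores):
            raise ValueError("AUROC needs y_true aligned with scores")
        classes = list(cm.class_names)
        S = np.array([[s.get(c, 0.0) for c in classes] for s in scores], dtype=float)
        if len(classes) == 2:
            y = np.array([1 if t == classes[1] else 0 for t in y_true])
            if len(set(y)) == 2:
                auroc = float(roc_auc_score(y, S[:, 1]))
        else:
            aucs = []
            for j, c in enumerate(classes):
                y = np.array([1 if t == c else 0 for t in y_true])
                if len(set(y)) == 2:
                    aucs.append(roc_auc_score(y, S[:, j]))
            auroc = float(np.mean(aucs)) if aucs else None

    return MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        auroc=auroc,
        n_evaluated=cm.total,
        n_abstained=n_abstained,
        notes=tuple(notes),
    )


def confidence_filter(
    predictions: Sequence[Prediction], cutoff: float
) -> tuple[list[Prediction], list[Prediction]]:
    """Partition predictions at the cutoff: accepted (confidence >= cutoff)
    and abstained (routed to manual review)."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    accepted = [p for p in predictions if p.confidence >= cutoff]
    abstained = [p for p in predictions if p.confidence < cutoff]
    return accepted, abstained


def confidence_curve(
    predictions: Sequence[Prediction], true_labels: Mapping[str, str]
) -> pd.DataFrame:
    """One row per distinct confidence value: (cutoff, n_accepted,
    accuracy_on_accepted).  n_accepted is non-increasing in cutoff by
    construction; accuracy on an empty accepted set is NaN."""
    rows = []
    for cutoff in sorted({p.confidence for p in predictions}):
        accepted, _ = confidence_filter(predictions, cutoff)
        if accepted:
            acc = sum(
                1 for p in accepted if p.predicted_label == true_labels[p.patient_id]
            ) / len(accepted)
        else:
            acc = math.nan
        rows.append({"cutoff": cutoff, "n_accepted": len(accepted), "accuracy_on_accepted": acc})
    return pd.DataFrame(rows, columns=["cutoff", "n_accepted", "accuracy_on_accepted"])


class BlindedSet:
    """Held-out patient vectors with sealed labels.

    The vectors are exposed label-free for prediction; the label map is
    private until :meth:`unblind` is called, which logs the event once and
    is idempotent afterwards.
    """

    def __init__(self, vectors: Sequence[PatientVector], labels: Mapping[str, str]):
        self._vectors = [
            PatientVector(v.patient_id, v.values, v.n_notes, label=None) for v in vectors
        ]
        self._sealed = dict(labels)
        self._unblinded = False
        self.log: list[str] = []

    @property
    def vectors(self) -> list[PatientVector]:
        return list(self._vectors)

    @property
    def is_unblinded(self) -> bool:
        return self._unblinded

    def unblind(self) -> Mapping[str, str]:
        if not self._unblinded:
            self._unblinded = True
            msg = f"unblinded labels for {len(self._sealed)} patients"
            self.log.append(msg)
            logger.info(msg)
        return dict(self._sealed)

    def labels(self) -> Mapping[str, str]:
        if not self._unblinded:
            raise BlindingError("labels are sealed; call unblind() first")
        return dict(self._sealed)


def make_blinded(vectors: Sequence[PatientVector]) -> BlindedSet:
    """Seal the labels of a labeled vector collection."""
    labels = {v.patient_id: v.label for v in vectors if v.label is not None}
    if len(labels) != len(vectors):
        missing = [v.patient_id for v in vectors if v.label is None]
        raise ValueError(f"blinded evaluation needs labeled patients; unlabeled: {missing}")
    return BlindedSet(vectors, labels)


def evaluate_blinded(model: TrainedModel, blinded: BlindedSet) -> list[Prediction]:
    """Predict on a blinded set without touching the sealed labels."""
    return predict(model, blinded.vectors)


def metrics_after_unblinding(
    blinded: BlindedSet, predictions: Sequence[Prediction]
) -> MetricsReport:
    """Unblind (logged) and compute the held-out metrics."""
    labels = blinded.unblind()
    cm = confusion(labels, predictions)
    y_true = [labels[p.patient_id] for p in predictions]
    scores = [p.class_scores for p in predictions]
    return compute_metrics(cm, y_true=y_true, scores=scores)


# --- report output ----------------------------------------------------------


def write_report_json(
    report: MetricsReport,
    cm: ConfusionMatrix,
    path: str | Path,
    curve: pd.DataFrame | None = None,
    kind: str = "held_out",
) -> None:
    """Machine-readable report; ``kind`` labels whether the accuracy is
    out-of-fold (training iterations) or held-out (after unblinding)."""
    payload = {
        "kind": kind,
        "confusion_matrix": {
            "class_names": list(cm.class_names),
            "counts": cm.counts.tolist(),
        },
        "metrics": report.to_dict(),
    }
    if curve is not None:
        payload["confidence_curve"] = curve.to_dict(orient="records")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")


def format_report_text(report: MetricsReport, cm: ConfusionMatrix) -> str:
    """Plain-text table for human review."""
    lines = [f"n evaluated: {report.n_evaluated}   abstained: {report.n_abstained}"]
    lines.append(f"accuracy: {report.accuracy:.3f}")
    if report.auroc is not None:
        lines.append(f"AUROC: {report.auroc:.3f}")
    width = max(len(c) for c in cm.class_names)
    header = " " * (width + 2) + "  ".join(f"{c:>{width}}" for c in cm.class_names)
    lines.append("confusion matrix (rows=true, cols=predicted):")
    lines.append(header)
    for i, c in enumerate(cm.class_names):
        row = "  ".join(f"{int(v):>{width}}" for v in cm.counts[i])
        lines.append(f"{c:<{width}}  {row}")
    lines.append(f"{'class':<{width}}  sens   spec   ppv    npv    f1")
    for c in cm.class_names:
        m = report.per_class[c]
        vals = "  ".join(
            "  nan" if math.isnan(m[k]) else f"{m[k]:.3f}"
            for k in ("sensitivity", "specificity", "ppv", "npv", "f1")
        )
        lines.append(f"{c:<{width}}  {vals}")
    if report.notes:
        lines += [f"note: {n}" for n in report.notes]
    return "\n".join(lines) + "\n"


def export_reviewed_predictions(
    predictions: Sequence[Prediction],
    true_labels: Mapping[str, str],
    path: str | Path,
) -> None:
    """Per-patient CSV with correctness flags, sortable by confidence —
    supports the error-review loop of finding patients the model was highly
    confident but wrong about."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "true_label", "predicted_label", "confidence", "correct"])
        for p in sorted(predictions, key=lambda p: -p.confidence):
            t = true_labels.get(p.patient_id, "")
            w.writerow([p.patient_id, t, p.predicted_label, repr(p.confidence), int(t == p.predicted_label)])
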