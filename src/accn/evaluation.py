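"""Classification metrics: confusion matrix, ACC/SEN/SPE, ROC and AUC.

Sensitivity is recall on the positive (abnormal) class, specificity recall
on the rest; for multi-class inputs both are one-vs-rest against the
configured positive class. AUC uses the rank (midrank-for-ties)
convention, so it equals the Mann-Whitney U statistic divided by
n_pos * n_neg exactly. scikit-learn does the counting behind this surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = ["EvalReport", "confusion_and_metrics", "auc_score",
           "roc_points", "evaluate_probabilities"]


@dataclass
class EvalReport:
    confusion: np.ndarray            # (N_c, N_c) ints; rows true, cols predicted
    acc: float
    sen: float | None                # None when no positive samples present
    spe: float | None                # None when no negative samples present
    auc: float | None = None
    roc: np.ndarray | None = None    # (n, 2) of (fpr, tpr)
    positive_class: int = 1

    def to_dict(self) -> dict:
        rnd = lambda v: None if v is None else round(float(v), 3)
        return {
            "confusion": self.confusion.astype(int).tolist(),
            "acc": rnd(self.acc), "sen": rnd(self.sen),
            "spe": rnd(self.spe), "auc": rnd(self.auc),
            "positive_class": int(self.positive_class),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        fmt = lambda v: "---" if v is None else f"{v:.3f}"
        return (f"ACC {fmt(self.acc)}  SEN {fmt(self.sen)}  "
                f"SPE {fmt(self.spe)}  AUC {fmt(self.auc)}")


def _as_labels(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr.astype(np.intp)


def confusion_and_metrics(predicted, true, positive_class: int = 1,
                          n_classes: int | None = None) -> EvalReport:
    """Exact integer confusion counts plus ACC/SEN/SPE (AUC not set here).

    SEN/SPE that are undefined (no positive / no negative samples in
    ``true``) are reported as None, never as 0.
    """
    y_pred = _as_labels(predicted, "predicted")
    y_true = _as_labels(true, "true")
    if len(y_pred) != len(y_true):
        raise ValueError(f"length mismatch: {len(y_pred)} predictions, "
                         f"{len(y_true)} true labels")
    if len(y_true) == 0:
        raise ValueError("cannot evaluate an empty label list")
    if n_classes is None:
        n_classes = int(max(y_pred.max(), y_true.max())) + 1
    if y_pred.min() < 0 or y_true.min() < 0 or max(y_pred.max(), y_true.max()) >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    if not (0 <= positive_class < n_classes):
        raise ValueError(f"positive_class {positive_class} outside [0, {n_classes})")

    conf = _skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = conf.sum()
    acc = float(np.trace(conf)) / total

    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    sen = float((y_pred[pos] == positive_class).mean()) if n_pos else None
    spe = float((y_pred[~pos] != positive_class).mean()) if n_neg else None
    return EvalReport(confusion=conf, acc=acc, sen=sen, spe=spe,
                      positive_class=positive_class)


def auc_score(scores, true_binary) -> float:
    """Area under the ROC curve of positive-class scores.

    Midrank tie handling makes this exactly U / (n_pos * n_neg). Raises on
    single-class input rather than returning a conventional value.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(true_binary).astype(np.intp)
    if len(s) != len(y):
        raise ValueError(f"length mismatch: {len(s)} scores, {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present in true labels")
    return float(_skm.roc_auc_score(y, s))


def roc_points(scores, true_binary) -> np.ndarray:
    """(fpr, tpr) pairs from all thresholds, from (0, 0) to (1, 1)."""
    y = np.asarray(true_binary).astype(np.intp)
    fpr, tpr, _ = _skm.roc_curve(y, np.asarray(scores, dtype=np.float64))
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], (0.0, 0.0)):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], (1.0, 1.0)):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def evaluate_probabilities(probs, true, positive_class: int = 1) -> EvalReport:
    """Full report from probability rows: argmax labels + one-vs-rest AUC/ROC."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError(f"probs must be (n, N_c), got shape {p.shape}")
    y_true = _as_labels(true, "true")
    report = confusion_and_metrics(np.argmax(p, axis=1), y_true,
                                   positive_class=positive_class,
                                   n_classes=p.shape[1])
    y_bin = (y_true == positive_class).astype(int)
    if len(np.unique(y_bin)) == 2:
        scores = p[:, positive_class]
        report.auc = auc_score(scores, y_bin)
        report.roc = roc_points(scores, y_bin)
    return report
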