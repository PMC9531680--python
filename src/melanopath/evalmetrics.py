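"""Shared evaluation metrics.

Covers confusion-matrix metrics for binary classifiers, greedy IoU matching
of detections with precision/recall/F1/Jaccard (detection Jaccard is the
box-level TP/(TP+FP+FN), which satisfies J = F1/(2-F1)), per-class Dice/IoU
for segmentation masks with unlabeled-pixel exclusion, and macro-averaged
multiclass metrics with rank-based AUC.

Metrics with a zero denominator are reported as NaN (undefined), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from . import palette as P
from .instances import InstanceSet

__all__ = ["ConfusionCounts", "DetectionScore", "confusion_metrics",
           "match_detections", "detection_prf", "prf_from_pr", "seg_overlap",
           "multiclass_metrics", "round_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    f1: float
    jaccard: float


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall/sensitivity, specificity and F1."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = (_ratio(2 * precision * recall, precision + recall)
          if not (math.isnan(precision) or math.isnan(recall)) else math.nan)
    return {
        "accuracy": _ratio(tp + tn, counts.total),
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": _ratio(tn, tn + fp),
        "f1": f1,
    }


def match_detections(predicted: InstanceSet, truth: InstanceSet,
                     iou_threshold: float = 0.5) -> ConfusionCounts:
    """Greedy one-to-one matching of predictions to ground-truth boxes.

    Predictions are visited in descending score order (ties broken by input
    order); each claims its highest-IoU unmatched truth box if that IoU
    reaches the threshold.  There are no true negatives in detection.
    """
    if iou_threshold < 0:
        raise ValueError("IoU threshold must be non-negative")
    scores = predicted.scores if predicted.scores is not None \
        else [1.0] * len(predicted)
    order = sorted(range(len(predicted)), key=lambda i: -scores[i])
    unmatched = set(range(len(truth)))
    tp = 0
    for i in order:
        best_j, best_iou = None, 0.0
        for j in unmatched:
            iou = predicted.boxes[i].iou(truth.boxes[j])
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None and best_iou >= iou_threshold:
            unmatched.remove(best_j)
            tp += 1
    return ConfusionCounts(tp=tp, tn=0, fp=len(predicted) - tp,
                           fn=len(unmatched))


def detection_prf(counts: ConfusionCounts) -> DetectionScore:
    """Precision/recall/F1 and box-level Jaccard TP/(TP+FP+FN)."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    else:
        f1 = _ratio(2 * precision * recall, precision + recall)
    return DetectionScore(precision=precision, recall=recall, f1=f1,
                          jaccard=_ratio(tp, tp + fp + fn))


def prf_from_pr(precision: float, recall: float) -> DetectionScore:
    """F1 and Jaccard implied by a printed precision/recall pair."""
    f1 = 2 * precision * recall / (precision + recall)
    jac = precision * recall / (precision + recall - precision * recall)
    return DetectionScore(precision=precision, recall=recall, f1=f1, jaccard=jac)


def seg_overlap(predicted: np.ndarray, truth: np.ndarray,
                classes) -> dict[str, dict[int, float] | float]:
    """Per-class and mean Dice/IoU; truth pixels labeled UL are excluded."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("mask dimension mismatch")
    valid = truth != P.UL
    dice: dict[int, float] = {}
    iou: dict[int, float] = {}
    for c in classes:
        a = (predicted == c) & valid
        b = (truth == c) & valid
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 and nb == 0:
            continue  # class absent from both masks: skipped, not scored 0
        inter = int((a & b).sum())
        dice[c] = 2.0 * inter / (na + nb)
        iou[c] = inter / (na + nb - inter)
    present = sorted(dice)
    return {
        "dice": dice,
        "iou": iou,
        "mean_dice": float(np.mean([dice[c] for c in present])) if present else math.nan,
        "mean_iou": float(np.mean([iou[c] for c in present])) if present else math.nan,
        "absent": [c for c in classes if c not in dice],
    }


def multiclass_metrics(probabilities: np.ndarray,
                       labels: np.ndarray) -> dict[str, float]:
    """Argmax accuracy plus macro one-vs-rest F1/sensitivity/specificity/AUC.

    AUC uses the Mann-Whitney rank statistic with midranks for ties (the
    computation behind ``roc_auc_score``).
    """
    prob = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if prob.ndim != 2:
        raise ValueError("probabilities must be (n_samples, n_classes)")
    if not np.allclose(prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("AUC undefined for single-class truth")
    pred = prob.argmax(axis=1)
    nclass = prob.shape[1]
    f1s, sens, specs, aucs = [], [], [], []
    for c in range(nclass):
        t = labels == c
        p = pred == c
        tp = int((t & p).sum()); fp = int((~t & p).sum())
        fn = int((t & ~p).sum()); tn = int((~t & ~p).sum())
        if tp + fn == 0:
            continue  # class absent from truth: skip in macro averages
        prec = _ratio(tp, tp + fp)
        rec = _ratio(tp, tp + fn)
        f1s.append(0.0 if (math.isnan(prec) or prec + rec == 0)
                   else 2 * prec * rec / (prec + rec))
        sens.append(rec)
        specs.append(_ratio(tn, tn + fp))
        aucs.append(roc_auc_score(t.astype(int), prob[:, c]))
    return {
        "accuracy": float((pred == labels).mean()),
        "macro_f1": float(np.mean(f1s)),
        "macro_sensitivity": float(np.mean(sens)),
        "macro_specificity": float(np.mean(specs)),
        "macro_auc": float(np.mean(aucs)),
    }


def round_table(values: dict[str, float], ndigits: int = 3) -> dict[str, float]:
    """Round metrics for report tables (3 decimals, round-half-even)."""
    return {k: round(v, ndigits) if isinstance(v, float) and not math.isnan(v)
            else v for k, v in values.items()}
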