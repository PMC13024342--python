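"""One-vs-rest evaluation metrics for the 3-class AD/HC/MCI task.

Per class, the 3x3 confusion matrix (rows = true, columns = predicted,
class order AD/HC/MCI, entries may be fractional for fold-averaged
matrices) is reduced one-vs-rest:

    sensitivity = TP/(TP+FN)      specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)      F1 = 2*P*R/(P+R)

Accuracy is trace/total; macro averages are unweighted class means;
macro AUC is one-vs-rest on predicted probabilities (scikit-learn).
Per-class metrics for a class absent from the truth are undefined and
excluded from macro averages with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .alignment import CLASS_ORDER

__all__ = ["MetricsReport", "confusion_matrix3", "metrics", "metrics_from_confusion", "aggregate"]


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro_sensitivity: float
    macro_precision: float
    macro_f1: float
    macro_specificity: float
    auc: float | None
    confusion: np.ndarray = field(repr=False)


def confusion_matrix3(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Counts with rows = true class, columns = predicted, order AD/HC/MCI."""
    cm = np.zeros((3, 3))
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[idx[t], idx[p]] += 1
    return cm


def metrics_from_confusion(
    cm: np.ndarray, scores_auc: float | None = None
) -> MetricsReport:
    """One-vs-rest metrics from a (possibly fractional) 3x3 confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    if cm.shape != (3, 3) or np.any(cm < 0):
        raise ValueError("need a nonnegative 3x3 confusion matrix")
    total = cm.sum()
    per_class: dict[str, dict[str, float]] = {}
    macro = {"sensitivity": [], "specificity": [], "precision": [], "f1": []}
    for i, cls in enumerate(CLASS_ORDER):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {cls} absent from y_true; metrics undefined")
            per_class[cls] = {k: np.nan for k in ("sensitivity", "specificity", "precision", "f1")}
            continue
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        per_class[cls] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "precision": float(prec),
            "f1": float(f1),
        }
        for k, v in per_class[cls].items():
            macro[k].append(v)
    return MetricsReport(
        accuracy=float(np.trace(cm) / total),
        per_class=per_class,
        macro_sensitivity=float(np.nanmean(macro["sensitivity"])),
        macro_precision=float(np.nanmean(macro["precision"])),
        macro_f1=float(np.nanmean(macro["f1"])),
        macro_specificity=float(np.nanmean(macro["specificity"])),
        auc=scores_auc,
        confusion=cm,
    )


def metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> MetricsReport:
    """Full report from labels (and optionally row-normalized probabilities)."""
    cm = confusion_matrix3(y_true, y_pred)
    auc = None
    if scores is not None:
        present = sorted(set(np.asarray(y_true)), key=CLASS_ORDER.index)
        if len(present) >= 2:
            cols = [CLASS_ORDER.index(c) for c in present]
            s = np.asarray(scores)[:, cols]
            s = s / s.sum(axis=1, keepdims=True)
            if len(present) == 2:
                auc = float(roc_auc_score(
                    (np.asarray(y_true) == present[1]).astype(int), s[:, 1]
                ))
            else:
                auc = float(
                    roc_auc_score(
                        y_true, s, multi_class="ovr", average="macro",
                        labels=present,
                    )
                )
    return metrics_from_confusion(cm, auc)


def aggregate(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean and SD of the headline metrics across folds or seeds."""
    out = {}
    for key in ("accuracy", "macro_sensitivity", "macro_precision", "macro_f1"):
        vals = np.array([getattr(r, key) for r in reports])
        out[key] = (float(vals.mean()), float(vals.std()))
    aucs = [r.auc for r in reports if r.auc is not None]
    if aucs:
        out["auc"] = (float(np.mean(aucs)), float(np.std(aucs)))
    return out
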