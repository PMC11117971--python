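"""Segmentation evaluation: pixel accuracy, per-class IoU, bootstrap CIs.

Two IoU conventions are provided. ``standard`` is the usual one-vs-rest
reading: for class k, FN counts only truth-k pixels predicted as something
else. ``paper_table1`` follows the confusion-matrix cell roles used in the
source method's evaluation protocol, where for class k every off-diagonal
cell that is not a false positive (prediction = k, truth != k) counts as a
false negative — including confusions between the *other two* classes.
Under that convention IoU is never larger than the standard one.

Rejection-aware evaluation drops rejected pixels (selection score below
threshold) and ignore-labeled pixels from the confusion matrix, and reports
the rejected fraction of valid pixels separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import select_pixels

IGNORE = 255
CLASS_NAMES = ("benign", "dcis", "idc")
N_CLASSES = 3


def confusion_matrix(pred, truth, accept=None) -> np.ndarray:
    """3x3 counts, rows = annotated class, columns = predicted class.

    Pixels with truth 255 or ``accept`` False are excluded. Prediction
    values must lie in {0, 1, 2} on the evaluated set (255 allowed only
    where excluded).
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same shape")
    keep = truth != IGNORE
    if accept is not None:
        keep &= np.asarray(accept, dtype=bool).ravel()
    p, t = pred[keep], truth[keep]
    if not (np.isin(p, np.arange(N_CLASSES)).all() and np.isin(t, np.arange(N_CLASSES)).all()):
        raise ValueError("labels outside {0,1,2,255}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (t.astype(int), p.astype(int)), 1)
    return cm


def pixel_accuracy(cm: np.ndarray) -> float:
    """Percent of evaluated pixels on the diagonal; NaN for an empty matrix."""
    total = cm.sum()
    if total == 0:
        return float("nan")
    return 100.0 * np.trace(cm) / total


def class_iou(cm: np.ndarray, k: int, mode: str = "paper_table1") -> float:
    """Intersection over union TP / (TP + FP + FN) for class ``k``.

    mode ``paper_table1``: FP = off-diagonal of column k; FN = *every other*
    off-diagonal cell (missed truth-k pixels and confusions among the other
    classes alike). mode ``standard``: FN = off-diagonal of row k only.
    Returns 1.0 when the class is absent and never predicted.
    """
    if k not in range(N_CLASSES):
        raise ValueError(f"unknown class {k}")
    cm = np.asarray(cm)
    tp = cm[k, k]
    fp = cm[:, k].sum() - tp
    if mode == "paper_table1":
        fn = cm.sum() - np.trace(cm) - fp
    elif mode == "standard":
        fn = cm[k, :].sum() - tp
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = tp + fp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def mean_iou(cm: np.ndarray, mode: str = "paper_table1") -> float:
    return float(np.mean([class_iou(cm, k, mode) for k in range(N_CLASSES)]))


def bootstrap_ci(
    per_unit_records: list,
    metric,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI over resampling units.

    Each record is a unit's confusion matrix (typically one per evaluation
    patch). A bootstrap replicate draws ``len(records)`` units with
    replacement, pools their matrices by summation and applies ``metric``
    to the pooled matrix; the 2.5th and 97.5th percentiles over ``n_boot``
    replicates are returned. Deterministic for a given seed.
    """
    if len(per_unit_records) == 0:
        raise ValueError("bootstrap_ci needs at least one unit")
    cms = np.stack([np.asarray(r) for r in per_unit_records])
    n = len(cms)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = metric(cms[idx].sum(axis=0))
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


@dataclass
class EvalReport:
    accuracy: float  # percent
    iou_per_class: dict  # class name -> IoU in [0, 1]
    miou: float
    rejection_fraction: float  # percent of valid pixels rejected
    mode: str = "paper_table1"
    ci: dict = field(default_factory=dict)  # metric name -> (low, high)
    n_units: int = 0
    confusion: np.ndarray | None = None

    def to_dict(self):
        d = {
            "accuracy": self.accuracy,
            "iou_per_class": self.iou_per_class,
            "miou": self.miou,
            "rejection_fraction": self.rejection_fraction,
            "mode": self.mode,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_units": self.n_units,
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d

    def to_json(self, path=None):
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_frame(self, model: str = "murss", coverage: float | None = None):
        """Flat one-row-per-metric table: model, coverage, metric, point,
        ci_low, ci_high."""
        rows = []
        metrics = {"accuracy": self.accuracy, "miou": self.miou}
        metrics.update({f"iou_{k}": v for k, v in self.iou_per_class.items()})
        metrics["rejection_fraction"] = self.rejection_fraction
        for name, val in metrics.items():
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append(
                {"model": model, "coverage": coverage, "metric": name,
                 "point": val, "ci_low": lo, "ci_high": hi}
            )
        return pd.DataFrame(rows)


def argmax_labels(O) -> np.ndarray:
    """Predicted labels from class scores; ties break to the lowest index
    (numpy argmax convention), which keeps evaluation deterministic."""
    O = np.asarray(O)
    axis = 1 if O.ndim == 4 else 0
    return O.argmax(axis=axis)


def evaluate_with_rejection(
    O,
    S,
    truth,
    threshold: float = 0.5,
    mode: str = "paper_table1",
    per_unit: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full rejection-aware evaluation of class scores against truth.

    Predictions are the per-pixel argmax of ``O``; the accepted set is
    ``S >= threshold``. Accuracy and IoU are computed over accepted,
    non-ignored pixels; ``rejection_fraction`` is the rejected percentage
    of non-ignored pixels. With ``per_unit`` (batched input) each batch
    element becomes a bootstrap unit and 95% CIs are attached for accuracy
    and mIoU. If every pixel is rejected the quality metrics are NaN and
    rejection is 100%.
    """
    O = np.asarray(O)
    S = S.data if hasattr(S, "data") else np.asarray(S)
    truth = np.asarray(truth)
    pred = argmax_labels(O)
    accept = select_pixels(S, threshold)
    valid = truth != IGNORE
    n_valid = int(valid.sum())
    rejected = float(100.0 * (valid & ~accept).sum() / max(n_valid, 1))
    cm = confusion_matrix(pred, truth, accept)
    if cm.sum() == 0:
        return EvalReport(
            accuracy=float("nan"),
            iou_per_class={k: float("nan") for k in CLASS_NAMES},
            miou=float("nan"),
            rejection_fraction=rejected,
            mode=mode,
            confusion=cm,
        )
    report = EvalReport(
        accuracy=pixel_accuracy(cm),
        iou_per_class={
            name: class_iou(cm, k, mode) for k, name in enumerate(CLASS_NAMES)
        },
        miou=mean_iou(cm, mode),
        rejection_fraction=rejected,
        mode=mode,
        confusion=cm,
    )
    if per_unit and O.ndim == 4 and O.shape[0] > 1:
        units = [
            confusion_matrix(pred[i], truth[i], accept[i]) for i in range(O.shape[0])
        ]
        report.n_units = len(units)
        report.ci = {
            "accuracy": bootstrap_ci(units, pixel_accuracy, n_boot, seed),
            "miou": bootstrap_ci(units, lambda c: mean_iou(c, mode), n_boot, seed),
        }
    return report
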