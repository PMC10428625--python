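"""Confusion-matrix metrics: OA, per-class accuracy, IoU/MIoU, Kappa.

Conventions: rows of the confusion matrix are ground truth, columns are
prediction; truth pixels labeled −1 (ignore) are excluded.  Per-class
accuracy is producer's accuracy (recall).  MIoU averages IoU over the
classes present in truth or prediction; a class absent from both is the
undefined 0/0 case and is excluded.  Kappa is the chance-corrected
agreement (p_o − p_e)/(1 − p_e).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .raster_io import CLASS_NAMES, IGNORE_LABEL


@dataclass
class ConfusionMatrix:
    """K×K count matrix; rows = truth, cols = prediction."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}×{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        header = "truth\\pred," + ",".join(self.class_names)
        rows = [
            f"{name}," + ",".join(str(v) for v in row)
            for name, row in zip(self.class_names, self.counts)
        ]
        with open(path, "w") as fh:
            fh.write("\n".join([header] + rows) + "\n")


def confusion_matrix(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int | None = None,
    class_names: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Count truth-vs-prediction pairs, ignoring truth == −1 pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred {pred.shape} and truth {truth.shape} differ in shape")
    valid = truth != IGNORE_LABEL
    if not np.any(valid):
        raise ValueError("no labeled pixels (all truth values are ignore)")
    t = truth[valid].ravel()
    p = pred[valid].ravel()
    if n_classes is None:
        n_classes = len(class_names) if class_names else int(max(t.max(), p.max())) + 1
    if class_names is None:
        class_names = (
            CLASS_NAMES
            if n_classes == len(CLASS_NAMES)
            else tuple(f"class{i}" for i in range(n_classes))
        )
    if t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes:
        raise ValueError("class ids outside [0, n_classes)")
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes), tuple(class_names))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: fraction of labeled pixels classified correctly."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Producer's accuracy (recall) per class; NaN where a class has no
    truth pixels (flagged with a warning)."""
    row = cm.counts.sum(axis=1)
    out = np.full(len(row), np.nan)
    nz = row > 0
    out[nz] = np.diag(cm.counts)[nz] / row[nz]
    if np.any(~nz):
        empty = [cm.class_names[i] for i in np.flatnonzero(~nz)]
        warnings.warn(f"classes with no truth pixels: {empty}", stacklevel=2)
    return out


def iou_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """IoU_i = cm[i,i] / (row_i + col_i − cm[i,i]); NaN when 0/0."""
    diag = np.diag(cm.counts).astype(np.float64)
    union = cm.counts.sum(axis=1) + cm.counts.sum(axis=0) - diag
    out = np.full(len(diag), np.nan)
    nz = union > 0
    out[nz] = diag[nz] / union[nz]
    return out


def miou(cm: ConfusionMatrix) -> tuple[float, np.ndarray]:
    """Mean IoU over classes present in truth or prediction."""
    iou = iou_per_class(cm)
    defined = ~np.isnan(iou)
    if not np.any(defined):
        raise ValueError("no class present in truth or prediction")
    return float(np.nanmean(iou)), iou


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (p_o − p_e)/(1 − p_e); NaN for the degenerate p_e = 1."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / (n * n)
    if p_e >= 1.0 - 1e-15:
        warnings.warn("kappa undefined: expected agreement is 1", stacklevel=2)
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class MetricsReport:
    oa: float
    per_class_accuracy: np.ndarray
    iou: np.ndarray
    miou: float
    kappa: float
    class_names: tuple[str, ...] = CLASS_NAMES

    def to_dict(self) -> dict:
        def clean(x):
            return None if np.isnan(x) else float(x)

        return {
            "oa": clean(self.oa),
            "per_class_accuracy": {
                n: clean(v) for n, v in zip(self.class_names, self.per_class_accuracy)
            },
            "iou": {n: clean(v) for n, v in zip(self.class_names, self.iou)},
            "miou": clean(self.miou),
            "kappa": clean(self.kappa),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        names = tuple(d["per_class_accuracy"])

        def arr(m):
            return np.array([np.nan if m[n] is None else m[n] for n in names])

        return cls(
            oa=d["oa"],
            per_class_accuracy=arr(d["per_class_accuracy"]),
            iou=arr(d["iou"]),
            miou=d["miou"],
            kappa=d["kappa"],
            class_names=names,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def format_table(self) -> str:
        """Percent table with two decimals (OA/per-class in %, MIoU and
        Kappa ×100)."""
        lines = [
            f"{n:<12s}{100 * a:8.2f}%"
            for n, a in zip(self.class_names, self.per_class_accuracy)
        ]
        lines.append(f"{'OA (%)':<12s}{100 * self.oa:8.2f}")
        lines.append(f"{'MIoU x100':<12s}{100 * self.miou:8.2f}")
        lines.append(f"{'Kappa x100':<12s}{100 * self.kappa:8.2f}")
        return "\n".join(lines)


def evaluate_run(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int | None = None,
    class_names: tuple[str, ...] | None = None,
) -> MetricsReport:
    """Full metric report from prediction and truth rasters."""
    cm = confusion_matrix(pred, truth, n_classes=n_classes, class_names=class_names)
    m, iou = miou(cm)
    return MetricsReport(
        oa=overall_accuracy(cm),
        per_class_accuracy=per_class_accuracy(cm),
        iou=iou,
        miou=m,
        kappa=kappa(cm),
        class_names=cm.class_names,
    )
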