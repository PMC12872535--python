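"""Segmentation evaluation: Dice, HD95, pixel P/R/F1, fragmentation.

Conventions (documented rather than silent):

* Dice when a class is absent from both masks is reported as 1.0 with an
  ``undefined`` flag set — the comparison is vacuous, not perfect.
* HD95 is the 95th percentile of the symmetric boundary-to-boundary Euclidean
  distance, in millimetres; undefined (flagged, NaN) when the class is missing
  from either mask.
* Precision/recall/F1 are pixel-level from the C x C confusion matrix; macro
  averages skip classes absent from both masks.
* Fragmentation counts 4-connected components (8-connectivity behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

_CONN4 = ndimage.generate_binary_structure(2, 1)
_CONN8 = ndimage.generate_binary_structure(2, 2)


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")


def dice(pred: np.ndarray, gt: np.ndarray, cls: int) -> tuple[float, bool]:
    """Dice overlap for one class; returns ``(value, undefined_flag)``."""
    _check_shapes(pred, gt)
    a = pred == cls
    b = gt == cls
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, True
    return 2.0 * int((a & b).sum()) / (na + nb), False


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, _CONN4, border_value=0)
    return mask & ~eroded


def hd95(
    pred: np.ndarray,
    gt: np.ndarray,
    cls: int,
    spacing_mm: float = 1.0,
    percentile: float = 95.0,
) -> tuple[float, bool]:
    """Percentile symmetric surface distance in mm; ``percentile=100`` is the
    classic Hausdorff distance.  Flagged NaN when either surface is empty."""
    _check_shapes(pred, gt)
    pa = np.argwhere(_boundary(pred == cls))
    pb = np.argwhere(_boundary(gt == cls))
    if len(pa) == 0 or len(pb) == 0:
        return float("nan"), True
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    all_d = np.concatenate([d_ab, d_ba])
    return float(np.percentile(all_d, percentile) * spacing_mm), False


def confusion_matrix(pred: np.ndarray, gt: np.ndarray, n_classes: int) -> np.ndarray:
    _check_shapes(pred, gt)
    idx = gt.astype(np.int64).ravel() * n_classes + pred.astype(np.int64).ravel()
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def pixel_prf(pred: np.ndarray, gt: np.ndarray, n_classes: int) -> dict:
    """Per-class precision/recall/F1 plus overall accuracy and macro averages."""
    cm = confusion_matrix(pred, gt, n_classes)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    present = (cm.sum(axis=0) + cm.sum(axis=1)) > 0
    macro = lambda v: float(v[present].mean()) if present.any() else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": float(tp.sum() / cm.sum()),
        "macro_precision": macro(precision),
        "macro_recall": macro(recall),
        "macro_f1": macro(f1),
        "confusion": cm,
    }


def fragmentation(pred: np.ndarray, cls: int, eight_connected: bool = False) -> int:
    """Number of connected components of one predicted class."""
    structure = _CONN8 if eight_connected else _CONN4
    _, n = ndimage.label(pred == cls, structure=structure)
    return int(n)


@dataclass
class SegReport:
    """Aggregate over one (pred, gt) pair."""

    n_classes: int
    dice_per_class: np.ndarray
    dice_undefined: np.ndarray
    hd95_per_class: np.ndarray
    hd95_undefined: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float
    fragmentation_per_class: np.ndarray

    @property
    def mean_foreground_dice(self) -> float:
        vals = [
            self.dice_per_class[c]
            for c in range(1, self.n_classes)
            if not self.dice_undefined[c]
        ]
        return float(np.mean(vals)) if vals else float("nan")

    def as_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "dice": self.dice_per_class.tolist(),
            "dice_undefined": self.dice_undefined.tolist(),
            "hd95_mm": self.hd95_per_class.tolist(),
            "hd95_undefined": self.hd95_undefined.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "fragmentation": self.fragmentation_per_class.tolist(),
            "mean_foreground_dice": self.mean_foreground_dice,
        }


def evaluate_pair(
    pred: np.ndarray,
    gt: np.ndarray,
    n_classes: int,
    spacing_mm: float = 1.0,
    eight_connected: bool = False,
) -> SegReport:
    d = np.zeros(n_classes)
    du = np.zeros(n_classes, dtype=bool)
    h = np.zeros(n_classes)
    hu = np.zeros(n_classes, dtype=bool)
    frag = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        d[c], du[c] = dice(pred, gt, c)
        h[c], hu[c] = hd95(pred, gt, c, spacing_mm)
        frag[c] = fragmentation(pred, c, eight_connected)
    prf = pixel_prf(pred, gt, n_classes)
    return SegReport(
        n_classes=n_classes,
        dice_per_class=d,
        dice_undefined=du,
        hd95_per_class=h,
        hd95_undefined=hu,
        precision=prf["precision"],
        recall=prf["recall"],
        f1=prf["f1"],
        accuracy=prf["accuracy"],
        macro_f1=prf["macro_f1"],
        fragmentation_per_class=frag,
    )


def aggregate_reports(reports: list[SegReport]) -> dict:
    """Dataset-level means; per-class Dice/HD95 averaged over defined cases."""
    n_classes = reports[0].n_classes
    dice_mean = np.zeros(n_classes)
    hd_mean = np.zeros(n_classes)
    for c in range(n_classes):
        dv = [r.dice_per_class[c] for r in reports if not r.dice_undefined[c]]
        hv = [r.hd95_per_class[c] for r in reports if not r.hd95_undefined[c]]
        dice_mean[c] = np.mean(dv) if dv else np.nan
        hd_mean[c] = np.mean(hv) if hv else np.nan
    return {
        "dice_per_class": dice_mean.tolist(),
        "hd95_per_class_mm": hd_mean.tolist(),
        "mean_foreground_dice": float(
            np.mean([r.mean_foreground_dice for r in reports])
        ),
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "macro_f1": float(np.mean([r.macro_f1 for r in reports])),
        "mean_fragmentation_per_class": np.mean(
            [r.fragmentation_per_class for r in reports], axis=0
        ).tolist(),
        "n_images": len(reports),
    }
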