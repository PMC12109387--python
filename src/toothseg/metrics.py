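"""Segmentation metrics: confusion matrix, IoU/Dice/accuracy, tooth-type table.

Per class c, with TP_c / FP_c / FN_c read off a C×C confusion matrix
(rows = truth, columns = prediction):

    IoU_c  = TP_c / (TP_c + FN_c + FP_c)            (Jaccard)
    Dice_c = 2·TP_c / (FN_c + 2·TP_c + FP_c)        (F1)
    Acc_c  = TP_c / (TP_c + FN_c)                   (recall)
    OA     = trace / total
    mX     = unweighted mean over classes present in the ground truth

Dice and IoU obey Dice = 2·IoU/(1+IoU) exactly.  Tooth-type rows (T1..T8 +
gum) are computed from the quadrant-merged confusion matrix, mirroring
per-tooth-type reporting where the four quadrant instances of each position
count as one class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import LabelScheme

__all__ = ["ConfusionMatrix", "MetricsReport", "compute_metrics"]


@dataclass
class ConfusionMatrix:
    """Accumulable C×C count matrix; rows = true class, columns = predicted."""

    num_classes: int = 33
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((self.num_classes, self.num_classes), dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (self.num_classes, self.num_classes):
                raise ValueError("counts shape must be (C, C)")
            if (self.counts < 0).any():
                raise ValueError("counts must be nonnegative")

    def accumulate(self, pred_labels: np.ndarray, true_labels: np.ndarray) -> "ConfusionMatrix":
        """Add one cloud's point-wise predictions; returns self for chaining."""
        pred = np.asarray(pred_labels, dtype=np.int64).reshape(-1)
        true = np.asarray(true_labels, dtype=np.int64).reshape(-1)
        if len(pred) != len(true):
            raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(true)} labels")
        c = self.num_classes
        if ((pred < 0) | (pred >= c) | (true < 0) | (true >= c)).any():
            raise ValueError("labels out of range")
        np.add.at(self.counts, (true, pred), 1)
        return self

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise ValueError("class count mismatch")
        return ConfusionMatrix(self.num_classes, self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def merged(self, groups: np.ndarray) -> "ConfusionMatrix":
        """Merge classes by an integer group map (class index -> group index)."""
        groups = np.asarray(groups, dtype=np.int64)
        g = int(groups.max()) + 1
        # two-step merge: rows then columns
        rows = np.zeros((g, self.num_classes), dtype=np.int64)
        np.add.at(rows, groups, self.counts)
        merged = np.zeros((g, g), dtype=np.int64)
        np.add.at(merged.T, groups, rows.T)
        return ConfusionMatrix(g, merged)


def _per_class(counts: np.ndarray) -> dict[str, np.ndarray]:
    tp = np.diag(counts).astype(np.float64)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = tp / (tp + fn + fp)
        dice = 2 * tp / (fn + 2 * tp + fp)
        acc = tp / (tp + fn)
    return {"tp": tp, "fn": fn, "fp": fp, "iou": iou, "dice": dice, "acc": acc}


@dataclass
class MetricsReport:
    """Full metric set; all ratio values are fractions in [0, 1]."""

    overall_accuracy: float
    mean_class_accuracy: float
    mean_iou: float
    mean_dice: float
    per_class_iou: np.ndarray  # NaN for classes absent from ground truth
    per_class_dice: np.ndarray
    per_class_acc: np.ndarray
    present_classes: np.ndarray
    tooth_type_table: dict[str, dict[str, float]]  # name -> {iou, dice, acc}

    def as_dict(self) -> dict:
        return {
            "OA": self.overall_accuracy,
            "mAcc": self.mean_class_accuracy,
            "mIoU": self.mean_iou,
            "mDice": self.mean_dice,
            "per_class": {
                "iou": self.per_class_iou.tolist(),
                "dice": self.per_class_dice.tolist(),
                "acc": self.per_class_acc.tolist(),
            },
            "present_classes": self.present_classes.tolist(),
            "tooth_types": self.tooth_type_table,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def table(self) -> str:
        """Aligned text table: one row per tooth type, then overall scores."""
        lines = [f"{'type':<6}{'IoU %':>9}{'Dice %':>9}{'Acc %':>9}"]
        order = [f"T{i}" for i in range(1, 9)] + ["gum"]
        for name in order:
            row = self.tooth_type_table.get(name)
            if row is None or np.isnan(row["iou"]):
                lines.append(f"{name:<6}{'-':>9}{'-':>9}{'-':>9}")
            else:
                lines.append(
                    f"{name:<6}{100 * row['iou']:>9.2f}"
                    f"{100 * row['dice']:>9.2f}{100 * row['acc']:>9.2f}"
                )
        lines.append("-" * 33)
        lines.append(f"{'OA':<6}{100 * self.overall_accuracy:>9.2f}")
        lines.append(f"{'mAcc':<6}{100 * self.mean_class_accuracy:>9.2f}")
        lines.append(f"{'mDice':<6}{100 * self.mean_dice:>9.2f}")
        lines.append(f"{'mIoU':<6}{100 * self.mean_iou:>9.2f}")
        return "\n".join(lines)


def compute_metrics(
    matrix: ConfusionMatrix,
    scheme: LabelScheme | None = None,
) -> MetricsReport:
    """All metrics from an accumulated confusion matrix.

    Macro means run over classes present in the ground truth (row sum > 0);
    absent classes are reported as NaN and excluded, matching per-cloud
    reporting practice when e.g. wisdom teeth are missing.
    """
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    counts = matrix.counts
    stats = _per_class(counts)
    present = counts.sum(axis=1) > 0
    oa = float(np.trace(counts) / counts.sum())
    report = MetricsReport(
        overall_accuracy=oa,
        mean_class_accuracy=float(np.nanmean(stats["acc"][present])),
        mean_iou=float(np.nanmean(stats["iou"][present])),
        mean_dice=float(np.nanmean(stats["dice"][present])),
        per_class_iou=np.where(present, stats["iou"], np.nan),
        per_class_dice=np.where(present, stats["dice"], np.nan),
        per_class_acc=np.where(present, stats["acc"], np.nan),
        present_classes=np.flatnonzero(present),
        tooth_type_table={},
    )
    if scheme is None:
        scheme = LabelScheme(num_classes=matrix.num_classes)
    if matrix.num_classes == scheme.num_classes == 33:
        groups = np.array([scheme.type_index(c) for c in range(33)])
        merged = matrix.merged(groups)
        mstats = _per_class(merged.counts)
        mpresent = merged.counts.sum(axis=1) > 0
        for gi, name in enumerate(scheme.type_names):
            if mpresent[gi]:
                report.tooth_type_table[name] = {
                    "iou": float(mstats["iou"][gi]),
                    "dice": float(mstats["dice"][gi]),
                    "acc": float(mstats["acc"][gi]),
                }
            else:
                report.tooth_type_table[name] = {
                    "iou": float("nan"), "dice": float("nan"), "acc": float("nan"),
                }
    return report
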