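"""Voxel-wise and segment-wise evaluation.

Per-class F1 (harmonic mean of precision and recall), macro F1 (mF1,
unweighted mean of per-class F1) and balanced class accuracy (bAcc,
unweighted mean of per-class recall), computed either over voxels or — after
segment washing — over segments, where every segment contributes a single
(ground truth, prediction) pair so scores are not skewed by segment size.
Background and non-annotated classes are excluded from all metrics; classes
without ground-truth support in an evaluation set are excluded from the
macro means (missing-segment subjects make empty classes routine) and their
count is reported.

Per-class F1 is categorized as excellent (> 0.9), good (> 0.75), moderate
(> 0.6) or poor (otherwise); boundaries are half-open so every score falls
in exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SegmentTable
from .grid import VolumeGrid
from .taxonomy import BACKGROUND, NON_ANNOTATED

__all__ = [
    "ConfusionCounts", "MetricsReport", "voxel_confusion", "scores",
    "segment_scores", "crossfold_summary", "performance_category",
    "error_map", "DEFAULT_EXCLUDE",
]

DEFAULT_EXCLUDE = frozenset({BACKGROUND, NON_ANNOTATED})


def performance_category(f1: float) -> str:
    if f1 > 0.9:
        return "excellent"
    if f1 > 0.75:
        return "good"
    if f1 > 0.6:
        return "moderate"
    return "poor"


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN over an explicit class universe."""

    class_indices: np.ndarray    # included classes, ascending
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    excluded: set[int] = field(default_factory=set)

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn


@dataclass
class MetricsReport:
    level: str                       # "voxel" | "segment"
    per_class: pd.DataFrame          # index class, columns f1/recall/precision/support/category
    mf1: float
    bacc: float
    n_skipped_classes: int
    fold_id: int | None = None

    def to_json_dict(self) -> dict:
        return {"level": self.level, "mf1": self.mf1, "bacc": self.bacc,
                "n_skipped_classes": self.n_skipped_classes, "fold_id": self.fold_id,
                "per_class": self.per_class.reset_index().to_dict(orient="records")}


def _as_array(x) -> np.ndarray:
    return np.asarray(x.data if isinstance(x, VolumeGrid) else x)


def _pair_confusion(gt: np.ndarray, pred: np.ndarray, exclude: set[int],
                    n_classes: int | None = None) -> ConfusionCounts:
    gt = gt.ravel().astype(np.int64)
    pred = pred.ravel().astype(np.int64)
    K = int(max(gt.max(initial=0), pred.max(initial=0))) + 1 if n_classes is None else n_classes
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (gt, pred), 1)
    included = np.array(sorted(set(range(K)) - set(exclude)), dtype=int)
    tp = cm[included, included]
    fn = cm[included, :].sum(axis=1) - tp     # any wrong prediction, incl. excluded classes
    fp = cm[:, included].sum(axis=0) - tp     # predictions of c on any other gt
    return ConfusionCounts(included, tp, fp, fn, set(exclude))


def voxel_confusion(gt, pred, exclude: set[int] = DEFAULT_EXCLUDE,
                    n_classes: int | None = None) -> ConfusionCounts:
    """Per-class TP/FP/FN over voxels.

    Excluded classes contribute no row of their own, but a prediction of an
    excluded class on an included-class voxel still counts as that class's
    FN (and an included-class prediction on an excluded voxel as FP).
    """
    g, p = _as_array(gt), _as_array(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    return _pair_confusion(g, p, set(exclude), n_classes)


def scores(conf: ConfusionCounts, level: str = "voxel",
           fold_id: int | None = None) -> MetricsReport:
    """Per-class F1/recall/precision and the macro means over included
    classes with ground-truth support."""
    support = conf.support
    has_support = support > 0
    if not has_support.any():
        raise ValueError("no included class has ground-truth support")

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 2 * conf.tp + conf.fp + conf.fn
        f1 = np.where(denom > 0, 2 * conf.tp / np.where(denom > 0, denom, 1), 0.0)
        recall = np.where(support > 0, conf.tp / np.where(support > 0, support, 1), 0.0)
        pdenom = conf.tp + conf.fp
        precision = np.where(pdenom > 0, conf.tp / np.where(pdenom > 0, pdenom, 1), 0.0)

    per_class = pd.DataFrame({
        "class_index": conf.class_indices, "f1": f1, "recall": recall,
        "precision": precision, "support": support,
        "category": [performance_category(v) for v in f1],
    }).set_index("class_index")

    mf1 = float(f1[has_support].mean())
    bacc = float(recall[has_support].mean())
    return MetricsReport(level, per_class, mf1, bacc,
                         n_skipped_classes=int((~has_support).sum()), fold_id=fold_id)


def segment_scores(table: SegmentTable, washed, exclude: set[int] = DEFAULT_EXCLUDE,
                   n_classes: int | None = None, fold_id: int | None = None) -> MetricsReport:
    """Segment-wise evaluation of a washed prediction.

    Every segment contributes one (gt_label, predicted label) pair; the
    prediction must be label-homogeneous within each segment (i.e. segment
    washing was applied), otherwise the input is rejected.
    """
    data = _as_array(washed)
    gt_pairs, pred_pairs = [], []
    for seg in table.segments:
        if seg.gt_label is None:
            raise ValueError(f"segment {seg.segment_id} has no ground-truth label")
        vals = np.unique(data[tuple(seg.voxels.T)])
        if len(vals) != 1:
            raise ValueError(
                f"segment {seg.segment_id} is not label-homogeneous "
                f"(labels {vals.tolist()}); apply segment washing first")
        gt_pairs.append(seg.gt_label)
        pred_pairs.append(int(vals[0]))
    conf = _pair_confusion(np.asarray(gt_pairs), np.asarray(pred_pairs),
                           set(exclude), n_classes)
    return scores(conf, level="segment", fold_id=fold_id)


def crossfold_summary(reports: list[MetricsReport]) -> dict:
    """Mean +/- sample standard deviation of mF1 and bAcc across folds,
    plus per-class mean F1 (the bar-chart-style per-segment summary)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 fold reports to summarize")
    levels = {r.level for r in reports}
    if len(levels) != 1:
        raise ValueError(f"cannot mix levels {sorted(levels)} in one summary")
    mf1 = np.array([r.mf1 for r in reports])
    bacc = np.array([r.bacc for r in reports])
    per_class = pd.concat([r.per_class["f1"] for r in reports], axis=1)
    return {
        "level": levels.pop(),
        "n_folds": len(reports),
        "mf1_mean": float(mf1.mean()), "mf1_std": float(mf1.std(ddof=1)),
        "bacc_mean": float(bacc.mean()), "bacc_std": float(bacc.std(ddof=1)),
        "per_class_f1_mean": per_class.mean(axis=1).to_dict(),
    }


def error_map(gt, pred, exclude: set[int] = DEFAULT_EXCLUDE) -> VolumeGrid:
    """Per-patient error volume: 1 where an included-class voxel is
    misclassified, 0 elsewhere (the error-map overlay for visual review)."""
    g = _as_array(gt)
    p = _as_array(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    wrong = (g != p) & ~np.isin(g, list(exclude))
    spacing = gt.spacing if isinstance(gt, VolumeGrid) else (1.0, 1.0, 1.0)
    return VolumeGrid(wrong.astype(np.uint8), spacing)
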