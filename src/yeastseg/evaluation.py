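"""Instance-segmentation evaluation.

A predicted cell is a true positive when its intersection-over-union with
the corresponding ground-truth cell is at least the threshold (default 50%);
predictions without a ground-truth match are false positives and vice versa
for false negatives.  Reported metrics are the accuracy TP/(TP+FP+FN) and
the mean IoU over true-positive pairs.  Correspondence is established by an
optimal one-to-one assignment maximizing total IoU over admissible pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "SegMetrics",
    "pairwise_iou",
    "match_cells",
    "compute_metrics",
    "evaluate",
    "evaluate_stack",
]


@dataclass
class MatchResult:
    tp_pairs: list[tuple[int, int, float]]  # (gt_id, pred_id, iou)
    fp_ids: list[int]
    fn_ids: list[int]
    iou_threshold: float


@dataclass
class SegMetrics:
    tp: int
    fp: int
    fn: int
    accuracy: float
    mean_iou_tp: float
    mean_iou_defined: bool = True


def pairwise_iou(
    gt: np.ndarray, pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IoU between every (gt, pred) label pair via the joint contingency table.

    Returns (iou_matrix, gt_ids, pred_ids) with iou_matrix[i, j] the IoU of
    gt_ids[i] against pred_ids[j]; disjoint pairs have IoU 0.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("ground truth and prediction shapes differ")
    gt_ids = np.unique(gt)
    gt_ids = gt_ids[gt_ids > 0]
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    if len(gt_ids) == 0 or len(pred_ids) == 0:
        return np.zeros((len(gt_ids), len(pred_ids))), gt_ids, pred_ids
    gt_idx = np.searchsorted(gt_ids, gt.ravel())
    pred_idx = np.searchsorted(pred_ids, pred.ravel())
    both = (gt.ravel() > 0) & (pred.ravel() > 0)
    joint = np.bincount(
        gt_idx[both] * len(pred_ids) + pred_idx[both],
        minlength=len(gt_ids) * len(pred_ids),
    ).reshape(len(gt_ids), len(pred_ids)).astype(float)
    area_gt = np.array([(gt == i).sum() for i in gt_ids], dtype=float)
    area_pred = np.array([(pred == j).sum() for j in pred_ids], dtype=float)
    union = area_gt[:, None] + area_pred[None, :] - joint
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, joint / union, 0.0)
    return iou, gt_ids, pred_ids


def match_cells(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """One-to-one matching maximizing total IoU over pairs with
    IoU >= ``iou_threshold`` (non-strict)."""
    iou, gt_ids, pred_ids = pairwise_iou(gt, pred)
    eligible = iou >= iou_threshold
    weights = np.where(eligible, iou, 0.0)
    tp_pairs: list[tuple[int, int, float]] = []
    if weights.size:
        rows, cols = linear_sum_assignment(weights, maximize=True)
        for i, j in zip(rows, cols):
            if eligible[i, j]:
                tp_pairs.append((int(gt_ids[i]), int(pred_ids[j]), float(iou[i, j])))
    matched_gt = {a for a, _, _ in tp_pairs}
    matched_pred = {b for _, b, _ in tp_pairs}
    return MatchResult(
        tp_pairs=sorted(tp_pairs),
        fp_ids=sorted(int(j) for j in pred_ids if j not in matched_pred),
        fn_ids=sorted(int(i) for i in gt_ids if i not in matched_gt),
        iou_threshold=iou_threshold,
    )


def compute_metrics(match: MatchResult) -> SegMetrics:
    """Accuracy TP/(TP+FP+FN) and mean IoU of true positives.

    Two empty masks score accuracy 1.0 by convention; with no true positives
    but some errors, the mean IoU is undefined and reported as 0 with
    ``mean_iou_defined = False``.
    """
    tp, fp, fn = len(match.tp_pairs), len(match.fp_ids), len(match.fn_ids)
    denom = tp + fp + fn
    accuracy = 1.0 if denom == 0 else tp / denom
    if tp > 0:
        mean_iou = float(np.mean([iou for _, _, iou in match.tp_pairs]))
        defined = True
    else:
        mean_iou, defined = 0.0, denom == 0
    return SegMetrics(tp=tp, fp=fp, fn=fn, accuracy=accuracy,
                      mean_iou_tp=mean_iou, mean_iou_defined=defined)


def evaluate(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5
) -> SegMetrics:
    """Convenience: match then compute metrics for one image."""
    return compute_metrics(match_cells(gt, pred, iou_threshold))


def evaluate_stack(
    gt_stack, pred_stack, iou_threshold: float = 0.5
) -> tuple[SegMetrics, list[SegMetrics]]:
    """Per-frame metrics plus pooled counts over a stack.

    Pooled accuracy uses summed TP/FP/FN; the pooled mean IoU averages over
    all TP pairs of all frames.
    """
    if len(gt_stack) != len(pred_stack):
        raise ValueError("stacks have different lengths")
    per_image: list[SegMetrics] = []
    all_ious: list[float] = []
    tp = fp = fn = 0
    for g, p in zip(gt_stack, pred_stack):
        m = match_cells(g, p, iou_threshold)
        per_image.append(compute_metrics(m))
        all_ious.extend(iou for _, _, iou in m.tp_pairs)
        tp += len(m.tp_pairs)
        fp += len(m.fp_ids)
        fn += len(m.fn_ids)
    denom = tp + fp + fn
    pooled = SegMetrics(
        tp=tp, fp=fp, fn=fn,
        accuracy=1.0 if denom == 0 else tp / denom,
        mean_iou_tp=float(np.mean(all_ious)) if all_ious else 0.0,
        mean_iou_defined=bool(all_ious) or denom == 0,
    )
    return pooled, per_image
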