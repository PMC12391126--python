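"""Segmentation evaluation: greedy mask matching, P/R/F1, AP and mAP ranges,
and convolution-layer complexity (FLOPs / parameter counts).

Matching uses mask IoU (pixel sets). Predictions are consumed in descending
confidence; each claims its best unmatched ground-truth instance when the
IoU clears the threshold (true positive), otherwise it counts as a false
positive; ground truths left unclaimed are false negatives. Average
precision integrates the all-point precision envelope over recall, the
convention of modern detection toolkits. For the single "leaf" class,
mAP50 equals AP at IoU 0.50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tracking import iou

MAP_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class EvalMatch:
    """TP/FP/FN bookkeeping from one GT-vs-prediction matching."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn

    @property
    def n_pred(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolutional layer: H x W feature map, C_in -> C_out channels,
    K x K kernel."""

    h: int
    w: int
    c_in: int
    c_out: int
    k: int

    def __post_init__(self) -> None:
        if min(self.h, self.w, self.c_in, self.c_out, self.k) <= 0:
            raise ValueError("all ConvLayerSpec fields must be positive")


def _match_flags(
    gt: list[np.ndarray],
    pred: list[tuple[np.ndarray, float]],
    iou_thresh: float,
) -> list[bool]:
    """Greedy confidence-ordered matching; returns per-prediction TP flags
    in descending-confidence order (stable for ties)."""
    order = sorted(range(len(pred)), key=lambda i: -pred[i][1])
    claimed = [False] * len(gt)
    flags = []
    for i in order:
        mask, _ = pred[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gt):
            if claimed[j]:
                continue
            v = iou(mask, g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thresh:
            claimed[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def match_predictions(
    gt: list[np.ndarray],
    pred: list[tuple[np.ndarray, float]],
    iou_thresh: float = 0.5,
) -> EvalMatch:
    """Match predicted masks to ground truth at one IoU threshold."""
    flags = _match_flags(gt, pred, iou_thresh)
    tp = sum(flags)
    return EvalMatch(tp=tp, fp=len(pred) - tp, fn=len(gt) - tp)


def precision_recall_f1(
    m: EvalMatch,
) -> tuple[float | None, float | None, float | None]:
    """P, R and F1; an undefined quantity (zero denominator) is None."""
    p = m.tp / m.n_pred if m.n_pred > 0 else None
    r = m.tp / m.n_gt if m.n_gt > 0 else None
    if p is None or r is None or (p + r) == 0:
        f1 = None
    else:
        f1 = 2 * p * r / (p + r)
    return p, r, f1


def pr_curve(
    gt: list[np.ndarray],
    pred: list[tuple[np.ndarray, float]],
    iou_thresh: float = 0.5,
) -> list[tuple[float, float]]:
    """(recall, precision) swept over the descending-confidence prefix of
    the predictions — one sample per prediction consumed."""
    if not gt:
        raise ValueError("PR curve needs at least one ground-truth instance")
    flags = _match_flags(gt, pred, iou_thresh)
    curve = []
    tp = 0
    for i, flag in enumerate(flags, start=1):
        tp += flag
        curve.append((tp / len(gt), tp / i))
    return curve


def average_precision(curve: list[tuple[float, float]]) -> float:
    """Area under the precision envelope over recall in [0, 1].

    All-point interpolation: precision at each recall is replaced by the
    maximum precision at any recall >= it, then the step function is
    integrated from recall 0.
    """
    if not curve:
        raise ValueError("empty PR curve")
    pts = sorted(curve)
    recalls = np.array([r for r, _ in pts])
    precisions = np.array([p for _, p in pts])
    if np.any((precisions < 0) | (precisions > 1)) or np.any(
        (recalls < 0) | (recalls > 1)
    ):
        raise ValueError("recall and precision must lie in [0, 1]")
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recalls, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate_ap(
    gt: list[np.ndarray],
    pred: list[tuple[np.ndarray, float]],
    iou_thresh: float = 0.5,
) -> float:
    """AP of a prediction set against ground truth at one IoU threshold."""
    if not pred:
        return 0.0
    return average_precision(pr_curve(gt, pred, iou_thresh))


def map_range(aps_by_threshold: dict[float, float]) -> tuple[float, float]:
    """(mAP50, mAP50-95) from per-threshold APs.

    mAP50 is the AP at threshold 0.50 (single class); mAP50-95 averages the
    ten thresholds 0.50, 0.55, ..., 0.95, all of which must be present.
    """
    keys = {round(k, 2): v for k, v in aps_by_threshold.items()}
    missing = [t for t in MAP_THRESHOLDS if t not in keys]
    if missing:
        raise ValueError(f"missing AP thresholds: {missing}")
    map50 = keys[0.50]
    map50_95 = float(np.mean([keys[t] for t in MAP_THRESHOLDS]))
    return map50, map50_95


def conv_flops_params(layer: ConvLayerSpec) -> tuple[int, int]:
    """FLOPs and parameter count of one convolutional layer.

    FLOPs = 2*H*W*(C_in*K^2 + 1)*C_out  (the +1 is the bias term);
    Params = C_in*K^2*C_out (weights only).
    """
    k2 = layer.k**2
    flops = 2 * layer.h * layer.w * (layer.c_in * k2 + 1) * layer.c_out
    params = layer.c_in * k2 * layer.c_out
    return flops, params


def evaluation_report(
    gt_frames: list[list[np.ndarray]],
    pred_frames: list[list[tuple[np.ndarray, float]]],
    iou_thresh: float = 0.5,
) -> dict:
    """Dataset-level report: pooled P/R/F1 at ``iou_thresh`` plus per-
    threshold AP, mAP50 and mAP50-95 over the standard threshold ladder.

    Frames are evaluated independently and pooled: TP/FP/FN counts add, and
    AP is computed per frame then averaged over frames with ground truth.
    """
    if len(gt_frames) != len(pred_frames):
        raise ValueError("gt and prediction frame lists differ in length")
    tp = fp = fn = 0
    for g, p in zip(gt_frames, pred_frames):
        m = match_predictions(g, p, iou_thresh)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    pooled = EvalMatch(tp=tp, fp=fp, fn=fn)
    p, r, f1 = precision_recall_f1(pooled)
    aps = {}
    for t in MAP_THRESHOLDS:
        frame_aps = [
            evaluate_ap(g, pr, t) for g, pr in zip(gt_frames, pred_frames) if g
        ]
        aps[t] = float(np.mean(frame_aps)) if frame_aps else math.nan
    map50, map50_95 = map_range(aps)
    return {
        "iou_threshold": iou_thresh,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": p,
        "recall": r,
        "f1": f1,
        "ap_by_threshold": aps,
        "mAP50": map50,
        "mAP50_95": map50_95,
    }
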