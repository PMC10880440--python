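"""Scoring predicted neuron masks against ground truth.

Matching is greedy one-to-one by descending IoU with a 0.5 default threshold;
recall/precision/F1 follow from the pooled true-positive counts.  Also
provides the per-neuron peak SNR used in detectability analyses and the
convex-hull mask-quality ratio (1 for soma-like convex masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .postprocess import iou as mask_iou


@dataclass
class MatchResult:
    pairs: list       # (pred_idx, gt_idx, iou)
    n_tp: int
    n_gt: int
    n_pred: int


@dataclass
class EvalResult:
    recall: float
    precision: float
    f1: float


def match_masks(pred: list, gt: list, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching by descending IoU above the threshold."""
    scores = []
    for i, pm in enumerate(pred):
        pm = np.asarray(pm, dtype=bool)
        for j, gm in enumerate(gt):
            v = mask_iou(pm, gm) if pm.any() or np.asarray(gm, dtype=bool).any() else 0.0
            if v >= iou_threshold:
                scores.append((v, i, j))
    scores.sort(key=lambda s: (-s[0], s[1], s[2]))
    used_p, used_g = set(), set()
    pairs = []
    for v, i, j in scores:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        pairs.append((i, j, v))
    return MatchResult(pairs=pairs, n_tp=len(pairs), n_gt=len(gt), n_pred=len(pred))


def precision_recall_f1(match: MatchResult) -> EvalResult:
    """Recall = TP/#GT, precision = TP/#Pred, F1 their harmonic mean."""
    if match.n_gt == 0 and match.n_pred == 0:
        raise ValueError("empty evaluation: no ground truth and no predictions")
    recall = match.n_tp / match.n_gt if match.n_gt else 0.0
    precision = match.n_tp / match.n_pred if match.n_pred else 0.0
    f1 = 0.0 if match.n_tp == 0 else 2.0 * recall * precision / (recall + precision)
    return EvalResult(recall=recall, precision=precision, f1=f1)


def frame_f1(pred_per_frame: list, gt_per_frame: list,
             iou_threshold: float = 0.5) -> float:
    """Pooled-count F1: frames matched independently, TP/GT/Pred summed."""
    if len(pred_per_frame) != len(gt_per_frame):
        raise ValueError("prediction and ground-truth frame lists differ in length")
    if len(pred_per_frame) == 0:
        raise ValueError("no labeled frames to evaluate")
    tp = n_gt = n_pred = 0
    for preds, gts in zip(pred_per_frame, gt_per_frame):
        n_gt += len(gts)
        n_pred += len(preds)
        if preds and gts:
            tp += match_masks(preds, gts, iou_threshold).n_tp
    if n_gt == 0 and n_pred == 0:
        raise ValueError("empty evaluation: no ground truth and no predictions")
    res = precision_recall_f1(MatchResult(pairs=[], n_tp=tp, n_gt=n_gt, n_pred=n_pred))
    return res.f1


def neuron_psnr(snr_video, mask: np.ndarray) -> float:
    """Peak SNR: max over frames of the mean SNR inside the mask."""
    frames = snr_video.frames if hasattr(snr_video, "frames") else np.asarray(snr_video)
    idx = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
    if idx.size == 0:
        raise ValueError("empty mask")
    trace = frames.reshape(frames.shape[0], -1)[:, idx].mean(axis=1)
    return float(trace.max())


def mask_quality(mask: np.ndarray) -> float:
    """Mask area divided by the area of its rasterized convex hull.

    The hull polygon is taken over pixel centers; a pixel belongs to the hull
    if its center lies inside or on the polygon.  Degenerate masks (< 3
    non-collinear pixels) score 1.
    """
    pix = np.argwhere(np.asarray(mask, dtype=bool))
    if len(pix) == 0:
        raise ValueError("empty mask")
    if len(pix) < 3:
        return 1.0
    try:
        hull = ConvexHull(pix.astype(np.float64))
    except QhullError:
        return 1.0  # collinear
    rmin, cmin = pix.min(axis=0)
    rmax, cmax = pix.max(axis=0)
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    # inside or on the hull: all facet equations <= 0 within tolerance
    a = hull.equations[:, :2]
    b = hull.equations[:, 2]
    inside = np.all(centers @ a.T + b <= 1e-9, axis=1)
    hull_area = int(inside.sum())
    return float(len(pix) / hull_area)
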