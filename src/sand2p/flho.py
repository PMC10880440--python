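"""Few Label Hyperparameter Optimization (FLHO).

Estimates the four postprocessing hyperparameters from the labeled frames
alone, in four steps:

1. For each labeled neuron, collect the median probability-map value inside
   its mask over its active labeled frames; the 25th percentile of those
   per-neuron medians is an intermediate threshold and the median, capped at
   0.8, becomes the final ``p_thresh``.
2. Grid-search ``min_area`` and ``centroid_dist`` to maximize frame-level F1
   on the labeled frames, binarizing at the intermediate threshold.
3. With the final ``p_thresh`` and chosen ``min_area``, find each neuron's
   longest run of consecutive frames with a colocalized detected component,
   using the probability maps of *all* frames.
4. ``min_consecutive`` is the second-smallest nonzero run count, capped at 8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .evaluate import frame_f1
from .postprocess import (Hyperparams, RoiComponent, binarize, extract_components,
                          components_colocalized, merge_components,
                          max_consecutive_run)
from .scenes import neuron_snr_traces

P_THRESH_CAP = 0.8
MIN_CONSECUTIVE_CAP = 8


class EstimationError(RuntimeError):
    """Raised when the labeled frames carry too little signal to estimate from."""


@dataclass
class NeuronProbabilityStat:
    neuron_id: int
    active_labeled_frames: list
    median_probability: float


@dataclass
class GridSpec:
    """Search grids for min_area (pixels) and centroid_dist (pixels)."""

    min_area_values: list
    centroid_dist_values: list

    def __post_init__(self):
        for vals in (self.min_area_values, self.centroid_dist_values):
            if len(vals) == 0 or np.any(np.diff(vals) <= 0):
                raise ValueError("grid values must be nonempty and strictly increasing")


def default_grid(soma_radius: float = 6.0) -> GridSpec:
    """Begin:step:end grids 30:10:150 px (area, scaled by (r/6)^2) and 2:1:10 px."""
    scale = (soma_radius / 6.0) ** 2
    areas = sorted({max(1, int(round(a * scale))) for a in range(30, 151, 10)})
    return GridSpec(min_area_values=areas, centroid_dist_values=list(range(2, 11)))


# ---------------------------------------------------------------------------
# step 1: p_thresh from per-neuron median probabilities
# ---------------------------------------------------------------------------

def neuron_active_frames(snr_video, gt_masks, activity_thresh: float) -> list:
    """Frames where each neuron's mean in-mask SNR exceeds activity_thresh."""
    frames = snr_video.frames if hasattr(snr_video, "frames") else np.asarray(snr_video)
    masks = np.asarray(gt_masks, dtype=bool)
    traces = neuron_snr_traces(frames, masks)
    out = []
    for i in range(len(masks)):
        active = set(np.flatnonzero(traces[i] > activity_thresh).tolist())
        if not active:
            warnings.warn(f"neuron {i} is silent at activity_thresh={activity_thresh}",
                          stacklevel=2)
        out.append(active)
    return out


def probability_distribution(prob_maps_labeled: np.ndarray, labeled_indices,
                             gt_masks, active_frames: list) -> list:
    """Per-neuron median of per-frame median in-mask probability.

    ``prob_maps_labeled`` is aligned with ``labeled_indices``; only active
    frames that are also labeled contribute.  Neurons with no active labeled
    frame are excluded.
    """
    labeled_indices = np.asarray(labeled_indices, dtype=int)
    pos = {int(f): i for i, f in enumerate(labeled_indices)}
    stats = []
    for nid, (mask, active) in enumerate(zip(np.asarray(gt_masks, dtype=bool),
                                             active_frames)):
        usable = sorted(set(int(f) for f in active) & set(pos))
        if not usable:
            continue
        idx = np.flatnonzero(mask.ravel())
        frame_medians = [float(np.median(prob_maps_labeled[pos[f]].ravel()[idx]))
                         for f in usable]
        stats.append(NeuronProbabilityStat(
            neuron_id=nid, active_labeled_frames=usable,
            median_probability=float(np.median(frame_medians))))
    if not stats:
        raise EstimationError(
            "no labeled neuron is active on a labeled frame; label more frames")
    return stats


def estimate_p_thresh(stats: list, intermediate_percentile: float = 25.0):
    """(intermediate, final) thresholds: 25th percentile and capped median."""
    if not stats:
        raise EstimationError("empty probability distribution")
    values = np.array([s.median_probability for s in stats])
    intermediate = float(np.percentile(values, intermediate_percentile))
    final = float(min(np.median(values), P_THRESH_CAP))
    return intermediate, final


# ---------------------------------------------------------------------------
# step 2: grid search for min_area and centroid_dist on the labeled frames
# ---------------------------------------------------------------------------

def _predictions_per_frame(records, labeled_positions):
    """final_mask of every record, placed on each labeled frame it is active on."""
    preds = [[] for _ in labeled_positions]
    pos = {f: i for i, f in enumerate(labeled_positions)}
    for r in records:
        for f in r.active_frames:
            preds[pos[f]].append(r.final_mask)
    return preds


def grid_search_spatial(prob_maps_labeled: np.ndarray, gt_on_labeled_frames: list,
                        intermediate_p_thresh: float, grid: GridSpec,
                        iou_threshold: float = 0.5):
    """Exhaustive (min_area, centroid_dist) search maximizing frame-level F1.

    Ties break toward smaller centroid_dist, then larger min_area.  Returns
    ((min_area, centroid_dist), f1_table) with the full score grid.
    """
    n_frames = len(prob_maps_labeled)
    base = [extract_components(binarize(m, intermediate_p_thresh), 1, t)
            for t, m in enumerate(prob_maps_labeled)]
    positions = list(range(n_frames))
    table = np.zeros((len(grid.min_area_values), len(grid.centroid_dist_values)))
    best = (-1.0, None)
    for ai, min_area in enumerate(grid.min_area_values):
        filtered = [c for frame in base for c in frame if c.area >= min_area]
        for di, cdist in enumerate(grid.centroid_dist_values):
            records = merge_components(filtered, cdist)
            preds = _predictions_per_frame(records, positions)
            try:
                f1 = frame_f1(preds, gt_on_labeled_frames, iou_threshold)
            except ValueError:
                f1 = 0.0
            table[ai, di] = f1
            key = (f1, -cdist, min_area)
            if best[1] is None or key > best[0]:
                best = (key, (min_area, cdist))
    return best[1], table


# ---------------------------------------------------------------------------
# steps 3-4: min_consecutive from per-neuron detection runs
# ---------------------------------------------------------------------------

def max_consecutive_per_neuron(prob_maps: np.ndarray, final_p_thresh: float,
                               min_area: int, gt_masks, centroid_dist: float) -> np.ndarray:
    """Longest run of frames with a surviving component colocalized per neuron."""
    masks = np.asarray(gt_masks, dtype=bool)
    refs = [RoiComponent.from_mask(m) for m in masks]
    detected = np.zeros((len(refs), len(prob_maps)), dtype=bool)
    for t, frame in enumerate(np.asarray(prob_maps)):
        comps = extract_components(binarize(frame, final_p_thresh), min_area, t)
        if not comps:
            continue
        for i, ref in enumerate(refs):
            detected[i, t] = any(
                components_colocalized(ref, c, centroid_dist) for c in comps)
    return np.array([max_consecutive_run(np.flatnonzero(row)) for row in detected])


def estimate_min_consecutive(counts) -> int:
    """Second-smallest nonzero run count, capped at 8 frames (floor 1)."""
    nonzero = sorted(int(c) for c in np.asarray(counts).ravel() if c > 0)
    if not nonzero:
        warnings.warn("no neuron was ever detected; min_consecutive falls back to 1",
                      stacklevel=2)
        return 1
    value = nonzero[1] if len(nonzero) >= 2 else nonzero[0]
    return max(1, min(value, MIN_CONSECUTIVE_CAP))


# ---------------------------------------------------------------------------
# the full pipeline, and the naive grid-search baseline
# ---------------------------------------------------------------------------

def run_flho(snr_video, prob_maps: np.ndarray, labeled_indices, gt_masks,
             grid: GridSpec | None = None, activity_thresh: float = 3.0,
             intermediate_percentile: float = 25.0, iou_threshold: float = 0.5,
             return_details: bool = False):
    """Estimate all four hyperparameters from the labeled frames only.

    ``gt_masks`` are the masks of the labeled neurons; probability maps must
    cover all frames.  Ground truth of unlabeled frames is never consulted.
    """
    grid = grid or default_grid()
    labeled_indices = np.asarray(labeled_indices, dtype=int)
    active = neuron_active_frames(snr_video, gt_masks, activity_thresh)
    maps_labeled = np.asarray(prob_maps)[labeled_indices]
    stats = probability_distribution(maps_labeled, labeled_indices, gt_masks, active)
    p_int, p_fin = estimate_p_thresh(stats, intermediate_percentile)

    gt_per_frame = []
    masks = np.asarray(gt_masks, dtype=bool)
    for f in labeled_indices:
        gt_per_frame.append([masks[i] for i in range(len(masks)) if int(f) in active[i]])
    (min_area, centroid_dist), table = grid_search_spatial(
        maps_labeled, gt_per_frame, p_int, grid, iou_threshold)

    counts = max_consecutive_per_neuron(prob_maps, p_fin, min_area, masks, centroid_dist)
    min_consecutive = estimate_min_consecutive(counts)

    hp = Hyperparams(p_thresh=p_fin, min_area=min_area,
                     centroid_dist=centroid_dist, min_consecutive=min_consecutive)
    if not return_details:
        return hp
    details = {
        "intermediate_p_thresh": p_int,
        "median_probabilities": [s.median_probability for s in stats],
        "stats": stats,
        "f1_table": table,
        "consecutive_counts": counts.tolist(),
    }
    return hp, details


def grid_search_baseline(prob_maps_labeled: np.ndarray, gt_on_labeled_frames: list,
                         grid: GridSpec | None = None, p_values=None,
                         iou_threshold: float = 0.5) -> Hyperparams:
    """Naive few-label grid search over p_thresh, min_area and centroid_dist.

    Emulates tuning every hyperparameter by maximizing F1 on the labeled
    frames alone.  Randomly sampled labeled frames contain no consecutive
    runs, so this baseline cannot estimate min_consecutive and uses 1.
    """
    grid = grid or default_grid()
    p_values = p_values if p_values is not None else [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
    best = None
    best_key = None
    for p in p_values:
        (min_area, cdist), table = grid_search_spatial(
            prob_maps_labeled, gt_on_labeled_frames, p, grid, iou_threshold)
        f1 = table.max()
        key = (f1, -p)  # prefer the lower threshold on ties, as a naive search does
        if best_key is None or key > best_key:
            best_key = key
            best = Hyperparams(p_thresh=p, min_area=min_area,
                               centroid_dist=cdist, min_consecutive=1)
    return best
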