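"""End-to-end orchestration: preprocess, train, infer, FLHO, postprocess, score.

``run_on_scene`` is the core experiment: it takes a synthetic scene with known
ground truth, emulates an annotator labeling the neurons visible on a few
randomly chosen frames, runs the full semi-supervised pipeline on those labels
only, and scores the final masks against all ground-truth footprints.
``run_pipeline`` is the file-based equivalent driven by a RunConfig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .evaluate import match_masks, precision_recall_f1, neuron_psnr, mask_quality
from .flho import (GridSpec, default_grid, run_flho, grid_search_baseline,
                   neuron_active_frames)
from .postprocess import Hyperparams, postprocess
from .preprocess import preprocess_video
from .scenes import SceneConfig, generate_scene, derive_temporal_masks, neuron_snr_traces
from .train import TrainConfig, LabeledSet, run_sand_training, select_training_frames

log = logging.getLogger("sand2p")


@dataclass
class RunConfig:
    video_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "run"
    scene: SceneConfig | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    grid: GridSpec | None = None
    activity_thresh: float = 3.0
    n_labeled_frames: int = 10
    seed: int = 0
    evaluate_against_scene: bool = True


def make_labeled_set(scene, video, snr_video, frame_indices,
                     activity_thresh: float) -> LabeledSet:
    """Emulate manual annotation of the chosen frames.

    A neuron counts as labeled if it is active (mean in-mask SNR above
    threshold) on at least one chosen frame; the per-frame targets are the
    unions of the labeled neurons' footprints active on that frame.
    """
    frame_indices = np.asarray(frame_indices, dtype=int)
    traces = neuron_snr_traces(snr_video.frames, scene.footprints)
    active = traces > activity_thresh
    labeled_neurons = np.flatnonzero(active[:, frame_indices].any(axis=1))
    if labeled_neurons.size == 0:
        raise ValueError("no neuron is active on the chosen frames; "
                         "label more frames or lower activity_thresh")
    h, w = scene.footprints.shape[1:]
    targets = np.zeros((len(frame_indices), h, w), dtype=bool)
    for k, f in enumerate(frame_indices):
        for i in labeled_neurons:
            if active[i, f]:
                targets[k] |= scene.footprints[i]
    return LabeledSet(frame_indices=frame_indices,
                      snr_frames=snr_video.frames[frame_indices],
                      temporal_masks=targets,
                      neuron_masks=scene.footprints[labeled_neurons])


def neuron_level_scores(records, gt_footprints, snr_video=None,
                        iou_threshold: float = 0.5) -> dict:
    """Score final masks against ground-truth footprints (neuron-level F1)."""
    pred = [r.final_mask for r in records]
    gt = [np.asarray(m, dtype=bool) for m in gt_footprints]
    match = match_masks(pred, gt, iou_threshold)
    res = precision_recall_f1(match)
    out = {"recall": res.recall, "precision": res.precision, "f1": res.f1,
           "n_tp": match.n_tp, "n_gt": match.n_gt, "n_pred": match.n_pred,
           "matched_iou": [float(v) for _, _, v in match.pairs],
           "mask_quality": [mask_quality(m) for m in pred] if pred else []}
    if snr_video is not None:
        out["gt_psnr"] = [neuron_psnr(snr_video, m) for m in gt]
    return out


def run_on_scene(config: SceneConfig, n_labeled_frames: int = 10,
                 train_cfg: TrainConfig | None = None,
                 grid: GridSpec | None = None, activity_thresh: float = 3.0,
                 intermediate_percentile: float = 25.0, seed: int | None = None,
                 return_artifacts: bool = False):
    """Full pipeline on a synthetic scene; returns the metrics dict.

    With ``return_artifacts`` also returns every intermediate artifact (scene,
    SNR video, model, probability maps, hyperparameters, records) so callers
    can rerun FLHO variants without retraining.
    """
    seed = config.seed if seed is None else seed
    train_cfg = train_cfg or TrainConfig(seed=seed)
    scene, video = generate_scene(config)

    frame_indices = select_training_frames(config.n_frames, n_labeled_frames, seed)

    # kernel from the neurons an annotator would see on those frames: use the
    # clean-signal activity to pick them, the raw video to cut transients
    visible = [i for i in range(scene.n_neurons)
               if scene.temporal_activity[i] & set(frame_indices.tolist())]
    kernel_masks = scene.footprints[visible] if visible else scene.footprints
    snr_video, kernel = preprocess_video(video, neuron_masks=kernel_masks)

    labeled = make_labeled_set(scene, video, snr_video, frame_indices, activity_thresh)
    log.info("labeled %d neurons on %d frames", labeled.labeled_neuron_count,
             len(frame_indices))

    artifacts = run_sand_training(snr_video, labeled, train_cfg)
    model = artifacts["model"]
    prob_maps = model.predict(snr_video.frames)

    grid = grid or default_grid(soma_radius=float(np.mean(config.soma_radius_range)))
    hp, details = run_flho(snr_video, prob_maps, frame_indices, labeled.neuron_masks,
                           grid, activity_thresh, intermediate_percentile,
                           return_details=True)
    records = postprocess(prob_maps, hp)
    metrics = neuron_level_scores(records, scene.footprints, snr_video)
    metrics["hyperparams"] = hp.to_dict()
    if not return_artifacts:
        return metrics
    artifacts.update({"scene": scene, "video": video, "snr_video": snr_video,
                      "kernel": kernel, "labeled": labeled, "prob_maps": prob_maps,
                      "hyperparams": hp, "flho_details": details,
                      "records": records, "metrics": metrics,
                      "frame_indices": frame_indices, "grid": grid,
                      "activity_thresh": activity_thresh})
    return metrics, artifacts


def rerun_flho_variant(artifacts: dict, intermediate_percentile: float) -> dict:
    """Re-estimate hyperparameters with a different intermediate percentile.

    Reuses the trained model's probability maps, so only FLHO and
    postprocessing are recomputed; returns the resulting metrics dict.
    """
    hp = run_flho(artifacts["snr_video"], artifacts["prob_maps"],
                  artifacts["frame_indices"], artifacts["labeled"].neuron_masks,
                  artifacts["grid"], artifacts["activity_thresh"],
                  intermediate_percentile)
    records = postprocess(artifacts["prob_maps"], hp)
    metrics = neuron_level_scores(records, artifacts["scene"].footprints)
    metrics["hyperparams"] = hp.to_dict()
    return metrics


def run_baseline_from_artifacts(artifacts: dict,
                                p_values=None) -> dict:
    """Single-model + naive grid-search baseline on an already-run scene.

    Uses the supervised-only variant-A ensemble member (no pseudolabel or
    fine-tune stages) and tunes p_thresh, min_area and centroid_dist by
    maximizing F1 on the labeled frames; min_consecutive stays at 1 because
    isolated random frames contain no consecutive runs to estimate it from.
    Pairs with the semi-supervised run on the identical scene and labels.
    """
    scene = artifacts["scene"]
    labeled = artifacts["labeled"]
    snr_video = artifacts["snr_video"]
    model = artifacts["ensemble"][0]
    prob_maps = model.predict(snr_video.frames)

    active = neuron_active_frames(snr_video, labeled.neuron_masks,
                                  artifacts["activity_thresh"])
    masks = np.asarray(labeled.neuron_masks, dtype=bool)
    gt_per_frame = [[masks[i] for i in range(len(masks)) if int(f) in active[i]]
                    for f in labeled.frame_indices]
    hp = grid_search_baseline(prob_maps[labeled.frame_indices], gt_per_frame,
                              artifacts["grid"], p_values)
    records = postprocess(prob_maps, hp)
    metrics = neuron_level_scores(records, scene.footprints)
    metrics["hyperparams"] = hp.to_dict()
    return metrics


def run_pipeline(config: RunConfig) -> dict:
    """File-based end-to-end run; persists every stage artifact in out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("pipeline start: seed=%d out=%s", config.seed, out)

    resolved = {
        "seed": config.seed,
        "n_labeled_frames": config.n_labeled_frames,
        "activity_thresh": config.activity_thresh,
        "train": config.train.to_dict(),
        "scene": config.scene.to_dict() if config.scene is not None else None,
        "video_path": config.video_path,
        "labels_path": config.labels_path,
    }
    (out / "config.json").write_text(_json_dumps(resolved))

    if config.scene is not None:
        metrics, art = run_on_scene(
            config.scene, config.n_labeled_frames, config.train, config.grid,
            config.activity_thresh, seed=config.seed, return_artifacts=True)
        sio.write_scene(out / "scene", art["scene"], art["video"], config.scene)
        labeled = art["labeled"]
    else:
        if config.video_path is None or config.labels_path is None:
            raise ValueError("need video and labels paths (or a scene config)")
        video = sio.read_video(config.video_path)
        idx, temporal, neurons = sio.read_labels(config.labels_path, video.shape)
        snr_video, kernel = preprocess_video(video, neuron_masks=neurons)
        labeled = LabeledSet(frame_indices=idx, snr_frames=snr_video.frames[idx],
                             temporal_masks=temporal, neuron_masks=neurons)
        art = run_sand_training(snr_video, labeled, config.train)
        prob_maps = art["model"].predict(snr_video.frames)
        grid = config.grid or default_grid()
        hp, details = run_flho(snr_video, prob_maps, idx, neurons, grid,
                               config.activity_thresh, return_details=True)
        records = postprocess(prob_maps, hp)
        art.update({"snr_video": snr_video, "kernel": kernel, "prob_maps": prob_maps,
                    "hyperparams": hp, "flho_details": details, "records": records})
        metrics = {"n_pred": len(records),
                   "hyperparams": hp.to_dict()}

    # persist stage artifacts
    if art.get("kernel") is not None:
        sio.save_kernel(out / "kernel.json", art["kernel"])
    np.save(out / "probability_maps.npy", art["prob_maps"])
    sio.write_labels(out / "labels.h5", labeled.frame_indices,
                     labeled.temporal_masks, labeled.neuron_masks)
    for name, model in [("final_A", art["model"])] + [
            (f"member_{m.variant}", m) for m in art["ensemble"]]:
        np.savez(out / f"weights_{name}.npz", **model.get_weights())
    np.save(out / "pseudolabels.npy", art["pseudolabels"].maps)
    sio.save_hyperparams(out / "hyperparams.json", art["hyperparams"],
                         art["flho_details"])
    sio.write_masks(out / "masks.h5", art["records"], art["prob_maps"].shape[1:])
    (out / "metrics.json").write_text(_json_dumps(metrics))
    (out / "loss_history.json").write_text(_json_dumps(art["histories"]))
    log.info("pipeline done: %d neurons", len(art["records"]))
    log.removeHandler(handler)
    handler.close()
    return metrics


def _json_dumps(obj) -> str:
    import json

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    return json.dumps(obj, indent=1, default=default)
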