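"""Reading and writing pipeline artifacts.

Videos travel as multi-page TIFF stacks or HDF5 files with a "video" dataset
(T x H x W, float32).  Labels, masks and ground truth use HDF5; small
provenance artifacts (kernel, hyperparameters, configs, metrics) use JSON or
YAML.  All coordinates are 0-based (row, col); frame indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .preprocess import CalciumKernel
from .postprocess import Hyperparams


def read_video(path) -> np.ndarray:
    """Load a T x H x W stack from TIFF or HDF5 (dataset "video")."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        video = tifffile.imread(path)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "video" not in f:
                raise ValueError(f"{path} has no 'video' dataset")
            video = f["video"][:]
    else:
        raise ValueError(f"unsupported video format: {path.suffix}")
    video = np.asarray(video)
    if video.ndim != 3:
        raise ValueError(f"expected a 3-D T x H x W stack, got shape {video.shape}")
    return video.astype(np.float32)


def write_video(path, video: np.ndarray) -> None:
    path = Path(path)
    video = np.asarray(video, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, video)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("video", data=video)
    else:
        raise ValueError(f"unsupported video format: {path.suffix}")


def write_labels(path, frame_indices, temporal_masks, neuron_masks) -> None:
    """Persist a labeled set: frame indices, per-frame targets, neuron masks."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frame_indices", data=np.asarray(frame_indices, dtype=np.int64))
        f.create_dataset("temporal_masks",
                         data=np.asarray(temporal_masks, dtype=np.uint8))
        f.create_dataset("neuron_masks", data=np.asarray(neuron_masks, dtype=np.uint8))


def read_labels(path, video_shape=None):
    """Load a labeled set, validating indices and mask geometry."""
    with h5py.File(path, "r") as f:
        idx = f["frame_indices"][:]
        temporal = f["temporal_masks"][:].astype(bool)
        neurons = f["neuron_masks"][:].astype(bool)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate labeled frame indices")
    if video_shape is not None:
        T, h, w = video_shape
        if idx.min(initial=0) < 0 or (len(idx) and idx.max() >= T):
            raise ValueError("labeled frame index out of range")
        if temporal.shape[1:] != (h, w) or (len(neurons) and neurons.shape[1:] != (h, w)):
            raise ValueError("label masks do not match the video dimensions")
    return idx, temporal, neurons


def write_masks(path, records, shape) -> None:
    """Final masks as HDF5 plus a JSON sidecar with per-record metadata."""
    path = Path(path)
    masks = np.zeros((len(records),) + tuple(shape), dtype=np.uint8)
    meta = []
    for i, r in enumerate(records):
        masks[i] = r.final_mask
        meta.append({"id": int(r.id), "area": int(r.final_mask.sum()),
                     "centroid": [float(c) for c in r.centroid],
                     "active_frames": [int(f) for f in r.active_frames]})
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=masks)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_masks(path):
    path = Path(path)
    with h5py.File(path, "r") as f:
        masks = f["masks"][:].astype(bool)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return masks, meta


def write_scene(out_dir, scene, video, config) -> None:
    """Synthetic scene: video.h5, ground_truth.h5 and a YAML config copy."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_video(out / "video.h5", video)
    with h5py.File(out / "ground_truth.h5", "w") as f:
        f.create_dataset("footprints", data=scene.footprints.astype(np.uint8))
        f.create_dataset("traces", data=scene.traces.astype(np.float32))
        pairs = [(i, t) for i, s in enumerate(scene.temporal_activity) for t in sorted(s)]
        f.create_dataset("active_frames",
                         data=np.asarray(pairs, dtype=np.int64).reshape(-1, 2))
    (out / "scene.yaml").write_text(yaml.safe_dump(config.to_dict()))


def read_scene_ground_truth(path):
    with h5py.File(path, "r") as f:
        footprints = f["footprints"][:].astype(bool)
        traces = f["traces"][:]
        pairs = f["active_frames"][:]
    active = [set() for _ in range(len(footprints))]
    for i, t in pairs:
        active[int(i)].add(int(t))
    return footprints, traces, active


def save_kernel(path, kernel: CalciumKernel) -> None:
    Path(path).write_text(json.dumps({"taps": kernel.taps.tolist(),
                                      "peak_index": int(kernel.peak_index)}))


def load_kernel(path) -> CalciumKernel:
    d = json.loads(Path(path).read_text())
    return CalciumKernel(taps=np.asarray(d["taps"]), peak_index=int(d["peak_index"]))


def save_hyperparams(path, hp: Hyperparams, details: dict | None = None) -> None:
    payload = hp.to_dict()
    if details:
        payload["details"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in details.items() if k != "stats"}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_hyperparams(path) -> Hyperparams:
    d = json.loads(Path(path).read_text())
    return Hyperparams(p_thresh=d["p_thresh"], min_area=d["min_area"],
                       centroid_dist=d["centroid_dist"],
                       min_consecutive=d["min_consecutive"])
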