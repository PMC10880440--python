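"""Semi-supervised training schedule.

Three ensemble members (U-Net variants A, B, C) are first trained on the few
manually labeled frames with the weighted focal+dice loss.  The trained
ensemble then predicts probability maps for unlabeled frames; the per-pixel
mean of the three outputs becomes a soft pseudolabel.  The variant-A network
continues training on the pseudolabels with binary cross-entropy and is
finally fine-tuned on the original labeled frames.

All randomness flows from a single integer seed through named child streams,
so a rerun with the same seed reproduces spike-for-spike identical training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .nets import UNet, Adam, LossConfig, combined_loss, bce_loss, build_unet


@dataclass
class TrainConfig:
    epochs_supervised: int = 200
    epochs_pseudo: int = 25
    epochs_finetune: int = 200
    learning_rate: float = 0.001
    batch_size: int = 20
    n_unlabeled: int = 1800
    augmentation: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs_supervised, self.epochs_pseudo, self.epochs_finetune) < 1:
            raise ValueError("all epoch counts must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.n_unlabeled < 1 or self.batch_size < 1:
            raise ValueError("n_unlabeled and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Reduced-epoch profile (50/10/50, batch 4) for desk-scale experiments."""
    params = dict(epochs_supervised=50, epochs_pseudo=10, epochs_finetune=50,
                  batch_size=4, seed=seed)
    params.update(overrides)
    return TrainConfig(**params)


@dataclass
class LabeledSet:
    """The few manually labeled frames and their per-frame activity masks."""

    frame_indices: np.ndarray        # labeled frame indices into the video
    snr_frames: np.ndarray           # (n, H, W) SNR frames at those indices
    temporal_masks: np.ndarray       # (n, H, W) bool training targets
    neuron_masks: np.ndarray         # (K, H, W) bool masks of labeled neurons

    def __post_init__(self):
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(np.unique(self.frame_indices)) != len(self.frame_indices):
            raise ValueError("labeled frame indices must be unique")
        if self.snr_frames.shape != self.temporal_masks.shape:
            raise ValueError("frames and masks must have identical shapes")

    @property
    def labeled_neuron_count(self) -> int:
        return len(self.neuron_masks)

    def __len__(self) -> int:
        return len(self.frame_indices)


@dataclass
class PseudolabelSet:
    """Soft targets for unlabeled frames: mean of the three ensemble outputs."""

    frame_indices: np.ndarray
    maps: np.ndarray                 # (n, H, W) in [0, 1]
    snr_frames: np.ndarray = None    # (n, H, W) inputs the maps were predicted from

    def __len__(self) -> int:
        return len(self.frame_indices)


def select_training_frames(snr_video, n_frames: int, seed: int) -> np.ndarray:
    """Uniformly sample distinct frame indices to present for manual labeling."""
    T = snr_video.frames.shape[0] if hasattr(snr_video, "frames") else int(snr_video)
    if not (1 <= n_frames <= T):
        raise ValueError(f"n_frames must be in [1, {T}]")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(T, size=n_frames, replace=False))


# ---------------------------------------------------------------------------
# augmentation: the dihedral group of the square
# ---------------------------------------------------------------------------

def apply_dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    """Apply transform k in 0..7: rotation by 90*(k%4) deg, then flip if k>=4."""
    out = np.rot90(arr, k % 4, axes=(-2, -1))
    if k >= 4:
        out = out[..., ::-1, :]
    return np.ascontiguousarray(out)


def augment(frame: np.ndarray, target: np.ndarray, seed) -> tuple:
    """Apply one random flip/rotation, identically to frame and target."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(rng.integers(8))
    return apply_dihedral(frame, k), apply_dihedral(target, k)


# ---------------------------------------------------------------------------
# training stages
# ---------------------------------------------------------------------------

def _train_loop(model: UNet, frames: np.ndarray, targets: np.ndarray,
                loss_and_grad, epochs: int, cfg: TrainConfig,
                rng: np.random.Generator) -> list:
    """Generic SGD loop shared by all stages; returns per-epoch mean loss."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n = len(frames)
    opt = Adam(model, lr=cfg.learning_rate)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb = frames[sel].astype(np.float32)
            tb = targets[sel].astype(np.float32)
            if cfg.augmentation:
                for j in range(len(sel)):
                    k = int(rng.integers(8))
                    xb[j] = apply_dihedral(xb[j], k)
                    tb[j] = apply_dihedral(tb[j], k)
            pred = model.forward(xb, train=True, rng=rng)
            grad = np.empty_like(pred)
            batch_loss = 0.0
            for j in range(len(sel)):
                lj, gj = loss_and_grad(pred[j], tb[j])
                batch_loss += lj
                grad[j] = gj
            grad /= len(sel)
            model.backward(grad)
            opt.step()
            losses.append(batch_loss / len(sel))
        history.append(float(np.mean(losses)))
    return history


def train_supervised(model: UNet, labeled: LabeledSet, cfg: TrainConfig,
                     loss_cfg: LossConfig | None = None,
                     rng: np.random.Generator | None = None,
                     epochs: int | None = None):
    """Stage 1/3: focal+dice training on the manually labeled frames."""
    if len(labeled) == 0:
        raise ValueError("labeled set is empty")
    loss_cfg = loss_cfg or LossConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    def lag(p, t):
        return combined_loss(p, t, loss_cfg, return_grad=True)

    history = _train_loop(model, labeled.snr_frames, labeled.temporal_masks,
                          lag, epochs or cfg.epochs_supervised, cfg, rng)
    return model, history


def generate_pseudolabels(ensemble: list, snr_video, labeled_indices,
                          n_unlabeled: int, seed) -> PseudolabelSet:
    """Stage 2: average the three members' probability maps on unlabeled frames."""
    if len(ensemble) != 3:
        raise ValueError("the ensemble must contain exactly three models")
    frames = snr_video.frames if hasattr(snr_video, "frames") else np.asarray(snr_video)
    T = frames.shape[0]
    remaining = np.setdiff1d(np.arange(T), np.asarray(labeled_indices, dtype=int))
    if n_unlabeled > len(remaining):
        warnings.warn(f"only {len(remaining)} unlabeled frames available; using all",
                      stacklevel=2)
        chosen = remaining
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        chosen = np.sort(rng.choice(remaining, size=n_unlabeled, replace=False))
    batch = frames[chosen]
    maps = np.zeros(batch.shape, dtype=np.float64)
    for model in ensemble:
        maps += model.predict(batch)
    maps /= len(ensemble)
    return PseudolabelSet(frame_indices=chosen, maps=maps.astype(np.float32),
                          snr_frames=np.asarray(batch, dtype=np.float32))


def train_on_pseudolabels(model: UNet, pseudo: PseudolabelSet, cfg: TrainConfig,
                          rng: np.random.Generator | None = None,
                          epochs: int | None = None):
    """Stage 3: continue the variant-A network on soft targets with BCE."""
    if len(pseudo) == 0:
        raise ValueError("pseudolabel set is empty")
    if pseudo.snr_frames is None:
        raise ValueError("pseudolabel set carries no input frames")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    def lag(p, t):
        return bce_loss(p, t, return_grad=True)

    history = _train_loop(model, pseudo.snr_frames, pseudo.maps,
                          lag, epochs or cfg.epochs_pseudo, cfg, rng)
    return model, history


def finetune(model: UNet, labeled: LabeledSet, cfg: TrainConfig,
             loss_cfg: LossConfig | None = None,
             rng: np.random.Generator | None = None):
    """Stage 4: a final focal+dice round on the original labeled frames."""
    return train_supervised(model, labeled, cfg, loss_cfg, rng,
                            epochs=cfg.epochs_finetune)


def run_sand_training(snr_video, labeled: LabeledSet, cfg: TrainConfig,
                      loss_cfg: LossConfig | None = None) -> dict:
    """Execute the full schedule and return every stage artifact.

    Returns a dict with the final model, the supervised ensemble, the
    pseudolabel set, and per-stage loss histories.
    """
    frames = snr_video.frames if hasattr(snr_video, "frames") else np.asarray(snr_video)
    keys = np.random.SeedSequence(cfg.seed).spawn(8)

    ensemble = []
    histories = {}
    for i, variant in enumerate("ABC"):
        model = UNet(variant, np.random.default_rng(keys[i]))
        rng = np.random.default_rng(keys[3 + i])
        model, hist = train_supervised(model, labeled, cfg, loss_cfg, rng)
        histories[f"supervised_{variant}"] = hist
        ensemble.append(model)

    pseudo_rng = np.random.default_rng(keys[6])
    pseudo = generate_pseudolabels(ensemble, frames, labeled.frame_indices,
                                   cfg.n_unlabeled, pseudo_rng)

    final = build_unet("A", 0)
    final.set_weights(ensemble[0].get_weights())  # continue the variant-A member
    rng = np.random.default_rng(keys[7])
    final, hist = train_on_pseudolabels(final, pseudo, cfg, rng)
    histories["pseudo"] = hist
    final, hist = finetune(final, labeled, cfg, loss_cfg, rng)
    histories["finetune"] = hist

    return {"model": final, "ensemble": ensemble, "pseudolabels": pseudo,
            "histories": histories}
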