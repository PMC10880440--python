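"""Shallow U-Net ensemble and segmentation losses.

Three tiny U-Net variants (A, B, C) share a three-level encoder layout and
differ only in decoder width.  Variant A is the final-prediction network; all
three are used to generate pseudolabels.  The networks are small enough
(< 10,000 trainable parameters each) that forward and backward passes are
implemented directly on NumPy arrays; gradients are exact and checked against
finite differences in the test suite.

Array convention: activations are float32 tensors of shape (N, C, H, W).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_CLIP = 1e-7  # probability clipping for log-based losses


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d:
    """Same-padding 2-D convolution with bias (zero padding, odd kernel)."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He initialization (ReLU body)
        self.w = (rng.standard_normal((c_out, c_in, ksize, ksize)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.ksize = ksize
        self.dw = None
        self.db = None
        self._cols = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.ksize
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        y = np.tensordot(cols, self.w, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,Cout)
        y += self.b
        if train:
            self._cols = cols
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.ksize
        p = k // 2
        cols = self._cols
        self.dw = np.tensordot(dy, cols, axes=([0, 2, 3], [0, 2, 3])).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        dyw = sliding_window_view(dyp, (k, k), axis=(2, 3))  # (N,Cout,H,W,k,k)
        wf = self.w[:, :, ::-1, ::-1]
        dx = np.tensordot(dyw, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,Cin)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2).astype(np.float32))


class ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        dr = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# U-Net variants
# ---------------------------------------------------------------------------

#: decoder channel widths, deepest level first
DECODER_CHANNELS = {"A": (10, 6), "B": (12, 8), "C": (16, 10)}
ENCODER_CHANNELS = (4, 8, 16)
DROPOUT_RATES = (0.1, 0.1, 0.2)


@dataclass
class UNetSpec:
    """Architecture description of one ensemble member."""

    variant: str
    depth: int = 3
    encoder_channels: tuple = ENCODER_CHANNELS
    decoder_channels: tuple = field(default=None)
    dropout_rates: tuple = DROPOUT_RATES
    skip_connections: tuple = (True, True)

    def __post_init__(self):
        if self.variant not in DECODER_CHANNELS:
            raise ValueError(f"unknown U-Net variant {self.variant!r}")
        if self.decoder_channels is None:
            self.decoder_channels = DECODER_CHANNELS[self.variant]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "depth": self.depth,
            "encoder_channels": list(self.encoder_channels),
            "decoder_channels": list(self.decoder_channels),
            "dropout_rates": list(self.dropout_rates),
        }


class UNet:
    """Three-level U-Net mapping one SNR frame to a per-pixel probability map.

    Layout: two 2x2 poolings, skip concatenations at the two upper levels,
    sigmoid output.  Spatial dims are reflect-padded to a multiple of 8 and
    the output cropped back.
    """

    def __init__(self, variant: str, rng: np.random.Generator):
        self.spec = UNetSpec(variant)
        e1, e2, e3 = self.spec.encoder_channels
        d2, d1 = self.spec.decoder_channels
        self.enc1 = Conv2d(1, e1, 3, rng)
        self.enc2 = Conv2d(e1, e2, 3, rng)
        self.enc3 = Conv2d(e2, e3, 3, rng)
        self.dec2 = Conv2d(e3 + e2, d2, 3, rng)
        self.dec1 = Conv2d(d2 + e1, d1, 3, rng)
        self.out = Conv2d(d1, 1, 1, rng)
        self.drop1 = Dropout(self.spec.dropout_rates[0])
        self.drop2 = Dropout(self.spec.dropout_rates[1])
        self.drop3 = Dropout(self.spec.dropout_rates[2])
        self.relu = [ReLU() for _ in range(5)]
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        self.up2, self.up1 = Upsample2(), Upsample2()

    # -- bookkeeping -------------------------------------------------------
    @property
    def variant(self) -> str:
        return self.spec.variant

    def conv_layers(self):
        return [self.enc1, self.enc2, self.enc3, self.dec2, self.dec1, self.out]

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self.conv_layers())

    def parameters(self):
        for i, c in enumerate(self.conv_layers()):
            yield f"conv{i}.w", c
            yield f"conv{i}.b", c

    def get_weights(self) -> dict:
        return {f"conv{i}.{a}": getattr(c, a).copy()
                for i, c in enumerate(self.conv_layers()) for a in ("w", "b")}

    def set_weights(self, weights: dict) -> None:
        for i, c in enumerate(self.conv_layers()):
            c.w = weights[f"conv{i}.w"].astype(np.float32).copy()
            c.b = weights[f"conv{i}.b"].astype(np.float32).copy()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Map (N, H, W) SNR frames to (N, H, W) probability maps."""
        if x.ndim != 3:
            raise ValueError("expected a (N, H, W) batch of frames")
        if train and rng is None:
            rng = np.random.default_rng()  # dropout needs a stream; unseeded fallback
        n, h, w = x.shape
        ph = (-h) % 8
        pw = (-w) % 8
        self._crop = (h, w)
        xb = x[:, None].astype(np.float32)
        if ph or pw:
            xb = np.pad(xb, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        self._pad = (ph, pw)

        a1 = self.drop1.forward(self.relu[0].forward(self.enc1.forward(xb, train), train),
                                train, rng)
        a2 = self.drop2.forward(self.relu[1].forward(
            self.enc2.forward(self.pool1.forward(a1, train), train), train), train, rng)
        a3 = self.drop3.forward(self.relu[2].forward(
            self.enc3.forward(self.pool2.forward(a2, train), train), train), train, rng)

        u2 = np.concatenate([self.up2.forward(a3, train), a2], axis=1)
        b2 = self.relu[3].forward(self.dec2.forward(u2, train), train)
        u1 = np.concatenate([self.up1.forward(b2, train), a1], axis=1)
        b1 = self.relu[4].forward(self.dec1.forward(u1, train), train)
        z = self.out.forward(b1, train)
        p = _sigmoid(z)
        self._p = p if train else None
        self._split2 = a3.shape[1]
        self._split1 = b2.shape[1]
        return p[:, 0, :h, :w]

    def backward(self, dldp: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability map); accumulates conv grads."""
        h, w = self._crop
        ph, pw = self._pad
        full = np.zeros_like(self._p)
        full[:, 0, :h, :w] = dldp
        dz = full * self._p * (1.0 - self._p)
        d = self.relu[4].backward(self.out.backward(dz))
        d = self.dec1.backward(d)
        dup1, da1_skip = d[:, : self._split1], d[:, self._split1:]
        d = self.relu[3].backward(self.up1.backward(dup1))
        d = self.dec2.backward(d)
        dup2, da2_skip = d[:, : self._split2], d[:, self._split2:]
        da3 = self.up2.backward(dup2)
        d = self.enc3.backward(self.relu[2].backward(self.drop3.backward(da3)))
        da2 = self.pool2.backward(d) + da2_skip
        d = self.enc2.backward(self.relu[1].backward(self.drop2.backward(da2)))
        da1 = self.pool1.backward(d) + da1_skip
        self.enc1.backward(self.relu[0].backward(self.drop1.backward(da1)))

    def predict(self, frames: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference over a (T, H, W) stack, returning a probability stack."""
        out = np.empty(frames.shape, dtype=np.float32)
        for i in range(0, len(frames), batch_size):
            out[i:i + batch_size] = self.forward(frames[i:i + batch_size], train=False)
        return out


def build_unet(variant: str, seed: int = 0) -> UNet:
    """Create an initialized ensemble member (variant 'A', 'B' or 'C')."""
    return UNet(variant, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# losses (each returns value, and the gradient w.r.t. pred when asked)
# ---------------------------------------------------------------------------

@dataclass
class LossConfig:
    """Weighted focal + dice loss. Only the 100:1 focal:dice ratio is fixed."""

    focal_weight: float = 1.0
    dice_weight: float = 0.01
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    dice_smooth: float = 1.0

    def __post_init__(self):
        ratio = self.focal_weight / self.dice_weight
        if not np.isclose(ratio, 100.0):
            raise ValueError("focal:dice weight ratio must be 100:1")
        if self.focal_gamma < 0 or not (0 < self.focal_alpha <= 1):
            raise ValueError("invalid focal parameters")


def _check_shapes(pred, target):
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")


def dice_loss(pred, target, smooth: float = 1.0, return_grad: bool = False):
    """1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s), summed over the map."""
    _check_shapes(pred, target)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    num = 2.0 * (pred * target).sum() + smooth
    den = pred.sum() + target.sum() + smooth
    loss = 1.0 - num / den
    if not return_grad:
        return loss
    grad = -(2.0 * target * den - num) / den ** 2
    return loss, grad


def focal_loss(pred, target, gamma: float = 2.0, alpha: float = 0.25,
               return_grad: bool = False):
    """Mean of -alpha * (1 - p_t)^gamma * log(p_t); p_t is the true-class prob."""
    _check_shapes(pred, target)
    p = np.clip(np.asarray(pred, dtype=np.float64), _CLIP, 1.0 - _CLIP)
    t = np.asarray(target, dtype=np.float64)
    pt = np.where(t > 0.5, p, 1.0 - p)
    one_m = 1.0 - pt
    loss = (-alpha * one_m ** gamma * np.log(pt)).mean()
    if not return_grad:
        return loss
    if gamma == 0.0:
        dpt = -alpha / pt
    else:
        dpt = -alpha * (-gamma * one_m ** (gamma - 1.0) * np.log(pt) + one_m ** gamma / pt)
    grad = np.where(t > 0.5, dpt, -dpt) / p.size
    return loss, grad


def bce_loss(pred, soft_target, return_grad: bool = False):
    """Mean binary cross-entropy against soft (real-valued) targets."""
    _check_shapes(pred, soft_target)
    p = np.clip(np.asarray(pred, dtype=np.float64), _CLIP, 1.0 - _CLIP)
    q = np.asarray(soft_target, dtype=np.float64)
    loss = -(q * np.log(p) + (1.0 - q) * np.log(1.0 - p)).mean()
    if not return_grad:
        return loss
    grad = (-(q / p) + (1.0 - q) / (1.0 - p)) / p.size
    return loss, grad


def combined_loss(pred, target, cfg: LossConfig | None = None,
                  return_grad: bool = False):
    """focal + 0.01 * dice (the 100:1 weighting used for supervised stages)."""
    cfg = cfg or LossConfig()
    if return_grad:
        f, gf = focal_loss(pred, target, cfg.focal_gamma, cfg.focal_alpha, True)
        d, gd = dice_loss(pred, target, cfg.dice_smooth, True)
        return (cfg.focal_weight * f + cfg.dice_weight * d,
                cfg.focal_weight * gf + cfg.dice_weight * gd)
    f = focal_loss(pred, target, cfg.focal_gamma, cfg.focal_alpha)
    d = dice_loss(pred, target, cfg.dice_smooth)
    return cfg.focal_weight * f + cfg.dice_weight * d


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a U-Net's conv layers (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: UNet, lr: float = 0.001):
        self.model = model
        self.lr = lr
        self.t = 0
        self.m = {}
        self.v = {}
        for i, c in enumerate(model.conv_layers()):
            for a in ("w", "b"):
                key = f"{i}.{a}"
                self.m[key] = np.zeros_like(getattr(c, a))
                self.v[key] = np.zeros_like(getattr(c, a))

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, c in enumerate(self.model.conv_layers()):
            for a in ("w", "b"):
                g = getattr(c, "d" + a)
                key = f"{i}.{a}"
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mhat = self.m[key] / bias1
                vhat = self.v[key] / bias2
                upd = getattr(c, a) - self.lr * mhat / (np.sqrt(vhat) + eps)
                setattr(c, a, upd.astype(np.float32))
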