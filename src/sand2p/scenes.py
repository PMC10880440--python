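"""Synthetic two-photon-like scenes with known ground truth.

Generates videos of elliptical somas whose fluorescence follows spike-driven
double-exponential calcium transients over a slowly drifting neuropil
background plus Gaussian shot-noise.  Every downstream stage of the pipeline
is testable against the exact footprints, spike times and activity sets that
the generator records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter


class ConfigurationError(ValueError):
    """Raised for an invalid scene configuration."""


class CapacityError(RuntimeError):
    """Raised when the requested neurons cannot be placed at the overlap cap."""


@dataclass
class SceneConfig:
    field_height: int = 64
    field_width: int = 64
    n_frames: int = 1000
    n_neurons: int = 20
    soma_radius_range: tuple = (3.0, 5.0)
    max_pairwise_overlap: float = 0.15
    spike_rate: float = 0.01          # Bernoulli events per frame per neuron
    transient_rise: float = 2.0       # frames
    transient_decay: float = 8.0      # frames
    transient_amplitude_range: tuple = (8.0, 12.0)  # peak dF, intensity units
    baseline: float = 20.0
    noise_sigma: float = 1.0
    neuropil_amplitude: float = 1.0
    min_soma_gap: float = 2.0         # clearance between soma boundaries, pixels
    seed: int = 0

    def __post_init__(self):
        if min(self.field_height, self.field_width, self.n_frames, self.n_neurons) <= 0:
            raise ConfigurationError("all sizes must be positive")
        if not (0 <= self.max_pairwise_overlap < 1):
            raise ConfigurationError("max_pairwise_overlap must be in [0, 1)")
        if not (self.transient_decay > self.transient_rise > 0):
            raise ConfigurationError("need transient_decay > transient_rise > 0")
        if self.soma_radius_range[0] > self.soma_radius_range[1] or self.soma_radius_range[0] <= 0:
            raise ConfigurationError("invalid soma_radius_range")
        if self.spike_rate < 0 or self.noise_sigma < 0:
            raise ConfigurationError("rates and noise must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthScene:
    footprints: np.ndarray            # (N, H, W) bool
    spike_times: list                 # per-neuron frame-index arrays
    traces: np.ndarray                # (N, T) noise-free fluorescence (baseline-free)
    temporal_activity: list = field(default_factory=list)  # per-neuron active-frame sets

    @property
    def n_neurons(self) -> int:
        return len(self.footprints)


def transient_kernel(rise: float, decay: float, length: int | None = None) -> np.ndarray:
    """Unit-peak double-exponential transient (1 - e^{-t/rise}) * e^{-t/decay}."""
    if length is None:
        length = int(np.ceil(rise + 8.0 * decay))
    t = np.arange(length, dtype=np.float64)
    k = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return k / k.max()


def kernel_peak_time(rise: float, decay: float) -> float:
    """Continuous-time maximum of the transient kernel: rise*ln(1 + decay/rise)."""
    return rise * np.log(1.0 + decay / rise)


def _neuron_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # one global stream per scene, split per neuron by index
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def generate_traces(config: SceneConfig, n: int):
    """Draw spike trains and render noise-free fluorescence traces.

    Each spike adds a unit-peak double-exponential kernel scaled by an
    amplitude drawn uniformly from ``transient_amplitude_range``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    T = config.n_frames
    kern = transient_kernel(config.transient_rise, config.transient_decay)
    spike_times = []
    traces = np.zeros((n, T), dtype=np.float64)
    for i in range(n):
        rng = _neuron_rng(config.seed, 0, i)
        spikes = np.flatnonzero(rng.random(T) < config.spike_rate)
        amps = rng.uniform(*config.transient_amplitude_range, size=len(spikes))
        for s, a in zip(spikes, amps):
            seg = kern[: T - s]
            traces[i, s:s + len(seg)] += a * seg
        spike_times.append(spikes)
    return spike_times, traces


def _rasterize_ellipse(h, w, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _place_footprints(config: SceneConfig, max_retries: int = 1000) -> np.ndarray:
    h, w = config.field_height, config.field_width
    lo, hi = config.soma_radius_range
    footprints = []
    areas = []
    centers = []
    max_radii = []
    for i in range(config.n_neurons):
        rng = _neuron_rng(config.seed, 1, i)
        placed = False
        for _ in range(max_retries):
            ry = rng.uniform(lo, hi)
            rx = rng.uniform(lo, hi)
            theta = rng.uniform(0, np.pi)
            m = max(ry, rx) + 1.0
            if 2 * m >= min(h, w):
                raise ConfigurationError("field too small for requested soma radii")
            cy = rng.uniform(m, h - 1 - m)
            cx = rng.uniform(m, w - 1 - m)
            # somatic exclusion: neighbouring cell bodies keep a neuropil gap
            if config.min_soma_gap > 0 and any(
                    np.hypot(cy - oy, cx - ox) < max(ry, rx) + orad + config.min_soma_gap
                    for (oy, ox), orad in zip(centers, max_radii)):
                continue
            fp = _rasterize_ellipse(h, w, cy, cx, ry, rx, theta)
            area = int(fp.sum())
            if area < 3:
                continue
            ok = True
            for other, oarea in zip(footprints, areas):
                cap = config.max_pairwise_overlap * min(area, oarea)
                if np.logical_and(fp, other).sum() > cap:
                    ok = False
                    break
            if ok:
                footprints.append(fp)
                areas.append(area)
                centers.append((cy, cx))
                max_radii.append(max(ry, rx))
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could only place {len(footprints)} of {config.n_neurons} neurons "
                f"at max_pairwise_overlap={config.max_pairwise_overlap}")
    return np.stack(footprints)


def generate_scene(config: SceneConfig):
    """Render (GroundTruthScene, video).

    video(t) = baseline + neuropil drift + sum_i trace_i(t) * footprint_i
               + N(0, noise_sigma).
    """
    h, w, T = config.field_height, config.field_width, config.n_frames
    footprints = _place_footprints(config)
    spike_times, traces = generate_traces(config, config.n_neurons)

    video = np.full((T, h, w), config.baseline, dtype=np.float64)

    if config.neuropil_amplitude > 0:
        rng_np = _neuron_rng(config.seed, 2, 0)
        fld = gaussian_filter(rng_np.standard_normal((h, w)), sigma=min(h, w) / 6.0)
        fld -= fld.min()
        if fld.max() > 0:
            fld /= fld.max()
        period = max(T / 2.0, 2.0)
        mod = 0.5 + 0.5 * np.sin(2.0 * np.pi * np.arange(T) / period)
        video += config.neuropil_amplitude * mod[:, None, None] * fld[None]

    fp32 = footprints.astype(np.float64)
    video += np.tensordot(traces.T, fp32, axes=(1, 0))

    # activity from the clean signal: frames with appreciable transient amplitude
    act_floor = 0.05 * config.transient_amplitude_range[0]
    temporal_activity = [set(np.flatnonzero(tr > act_floor).tolist()) for tr in traces]

    if config.noise_sigma > 0:
        rng_noise = _neuron_rng(config.seed, 3, 0)
        video += rng_noise.normal(0.0, config.noise_sigma, size=video.shape)

    scene = GroundTruthScene(footprints=footprints, spike_times=spike_times,
                             traces=traces, temporal_activity=temporal_activity)
    return scene, video.astype(np.float32)


def neuron_snr_traces(snr_frames: np.ndarray, footprints: np.ndarray) -> np.ndarray:
    """Per-neuron mean SNR inside the footprint at every frame: (N, T)."""
    T = snr_frames.shape[0]
    flat = snr_frames.reshape(T, -1)
    out = np.empty((len(footprints), T), dtype=np.float64)
    for i, fp in enumerate(footprints):
        idx = np.flatnonzero(fp.ravel())
        if idx.size == 0:
            raise ValueError(f"footprint {i} is empty")
        out[i] = flat[:, idx].mean(axis=1)
    return out


def derive_temporal_masks(scene: GroundTruthScene, snr_video, activity_thresh: float):
    """Per-frame binary targets: union of footprints of neurons active at t.

    A neuron is active at frame t when its mean SNR over footprint pixels
    exceeds ``activity_thresh``.  Returns (masks (T,H,W) bool, active_sets).
    """
    frames = snr_video.frames if hasattr(snr_video, "frames") else np.asarray(snr_video)
    if frames.shape[1:] != scene.footprints.shape[1:]:
        raise ValueError("SNR video shape does not match scene footprints")
    traces = neuron_snr_traces(frames, scene.footprints)
    active = traces > activity_thresh
    T = frames.shape[0]
    masks = np.zeros((T,) + scene.footprints.shape[1:], dtype=bool)
    active_sets = []
    for i, fp in enumerate(scene.footprints):
        on = np.flatnonzero(active[i])
        masks[on] |= fp
        active_sets.append(set(on.tolist()))
    return masks, active_sets


def easy_scene_config(seed: int = 0, **overrides) -> SceneConfig:
    """64x64x1000 scene of 20 neurons whose filtered peak SNR is ~10."""
    params = dict(field_height=64, field_width=64, n_frames=1000, n_neurons=20,
                  soma_radius_range=(2.5, 3.5),
                  transient_amplitude_range=(3.9, 4.7), noise_sigma=1.0,
                  spike_rate=0.012, seed=seed)
    params.update(overrides)
    return SceneConfig(**params)


def hard_scene_config(seed: int = 0, **overrides) -> SceneConfig:
    """Same geometry with roughly half the transient amplitude (peak SNR ~5)."""
    params = dict(field_height=64, field_width=64, n_frames=1000, n_neurons=20,
                  soma_radius_range=(2.5, 3.5),
                  transient_amplitude_range=(1.8, 2.2), noise_sigma=1.0,
                  spike_rate=0.012, seed=seed)
    params.update(overrides)
    return SceneConfig(**params)
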