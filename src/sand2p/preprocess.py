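"""SNR preprocessing: temporal matched filtering and noise normalization.

The registered video is convolved per pixel with a matched filter built from
the time-reversed average calcium transient of labeled neurons, then
re-expressed in noise units: (filtered - temporal median) / noise image.  The
noise image is the lower quantile spread (Q50 - Q25) / 0.6745, which is robust
to the positive-going transients that would inflate an upper-sided estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks

NOISE_FLOOR = 1e-6
#: Gaussian consistency factor: (Q50 - Q25) of N(0, 1) equals 0.6745 sigma
QUANTILE_SIGMA = 0.6745


@dataclass
class CalciumKernel:
    """Matched-filter taps (time-reversed transient, peak normalized to 1)."""

    taps: np.ndarray
    peak_index: int

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=np.float64)
        if self.taps.ndim != 1 or self.taps.size < 1:
            raise ValueError("kernel taps must be a nonempty 1-D vector")


@dataclass
class SNRVideo:
    """Noise-normalized video: frames = (filtered - median) / noise."""

    frames: np.ndarray        # (T, H, W), noise units
    median_image: np.ndarray  # (H, W)
    noise_image: np.ndarray   # (H, W), strictly positive

    @property
    def shape(self):
        return self.frames.shape


def _trace_to_snr_units(trace: np.ndarray) -> np.ndarray:
    med = np.median(trace)
    q25 = np.quantile(trace, 0.25)
    noise = max((med - q25) / QUANTILE_SIGMA, NOISE_FLOOR)
    return (trace - med) / noise


def extract_transients(video: np.ndarray, neuron_masks: np.ndarray,
                       pre: int = 6, post: int = 24,
                       min_peak_snr: float = 3.0) -> list[np.ndarray]:
    """Cut peak-centered transient snippets (SNR units) from mask-mean traces.

    Each labeled neuron's raw trace is the mean over its mask pixels; the
    trace is converted to SNR units and local maxima above ``min_peak_snr``
    become snippets of length pre + post + 1 with the peak at index ``pre``.
    """
    T = video.shape[0]
    flat = video.reshape(T, -1)
    snippets = []
    for mask in neuron_masks:
        idx = np.flatnonzero(np.asarray(mask).ravel())
        if idx.size == 0:
            continue
        snr = _trace_to_snr_units(flat[:, idx].mean(axis=1))
        peaks, _ = find_peaks(snr, height=min_peak_snr, distance=max(pre, 1))
        for p in peaks:
            if p - pre < 0 or p + post + 1 > T:
                continue
            snip = snr[p - pre: p + post + 1].copy()
            # reject windows dominated by a neighbouring transient: the
            # centred peak must be the window maximum for clean alignment
            if int(np.argmax(snip)) != pre:
                continue
            snippets.append(snip)
    return snippets


def build_matched_kernel(transients: list[np.ndarray], snr_lo: float = 5.0,
                         snr_hi: float = 8.0, trunc_frac: float = 0.05) -> CalciumKernel:
    """Average peak-aligned transients with peak SNR in [snr_lo, snr_hi].

    The average is truncated where its ends fall below ``trunc_frac`` of the
    peak, peak-normalized to 1, and time-reversed.  If no transient qualifies,
    all transients are averaged and a degraded-kernel warning is emitted.
    """
    transients = [np.asarray(t, dtype=np.float64) for t in transients]
    if not transients:
        raise ValueError("no transients supplied")
    qualifying = [t for t in transients if snr_lo <= t.max() <= snr_hi]
    if not qualifying:
        warnings.warn("no transient with peak SNR in range; kernel quality degraded",
                      stacklevel=2)
        qualifying = transients

    # peak-align: pad every snippet into a common frame around its argmax
    peaks = [int(np.argmax(t)) for t in qualifying]
    pre = max(peaks)
    post = max(len(t) - p - 1 for t, p in zip(qualifying, peaks))
    acc = np.zeros(pre + post + 1)
    cnt = np.zeros(pre + post + 1)
    for t, p in zip(qualifying, peaks):
        start = pre - p
        acc[start:start + len(t)] += t
        cnt[start:start + len(t)] += 1
    avg = acc / np.maximum(cnt, 1)

    peak = avg.max()
    if peak <= 0:
        raise ValueError("averaged transient has nonpositive peak")
    keep = avg >= trunc_frac * peak
    lo = int(np.argmax(keep))
    hi = len(keep) - int(np.argmax(keep[::-1]))
    avg = avg[lo:hi] / peak
    taps = avg[::-1].copy()
    return CalciumKernel(taps=taps, peak_index=int(np.argmax(taps)))


def temporal_filter(video: np.ndarray, kernel: CalciumKernel) -> np.ndarray:
    """Per-pixel matched filtering, output aligned to the transient peak.

    A pixel trace equal to the (unreversed) template attains its filtered
    maximum at the template's peak frame.  Boundaries are reflect-padded and
    the output has the input length.
    """
    video = np.asarray(video)
    T = video.shape[0]
    L = kernel.taps.size
    if L > T:
        raise ValueError("kernel longer than video")
    if L == 1:
        return video * kernel.taps[0]
    pad = min(L, T - 1)
    padder = [(pad, pad)] + [(0, 0)] * (video.ndim - 1)
    xp = np.pad(video, padder, mode="reflect")
    taps = kernel.taps.reshape((L,) + (1,) * (video.ndim - 1))
    conv = fftconvolve(xp.astype(np.float64), taps, mode="full", axes=0)
    start = pad + L - 1 - ((L - 1) - kernel.peak_index)
    return conv[start:start + T].astype(np.float32)


def snr_normalize(filtered: np.ndarray, noise_quantiles=(0.25, 0.5),
                  eps: float = NOISE_FLOOR) -> SNRVideo:
    """Pixel-wise (x - median) / noise with noise = (Q50 - Q25) / 0.6745."""
    filtered = np.asarray(filtered, dtype=np.float32)
    if filtered.shape[0] < 2:
        raise ValueError("need at least 2 frames for quantile noise estimation")
    if filtered.shape[0] < 10:
        warnings.warn("fewer than 10 frames; quantile noise estimate is crude",
                      stacklevel=2)
    q_lo, q_hi = sorted(noise_quantiles)
    lo, med = np.quantile(filtered, [q_lo, q_hi], axis=0)
    noise = np.maximum((med - lo) / QUANTILE_SIGMA, eps).astype(np.float32)
    med = med.astype(np.float32)
    frames = (filtered - med) / noise
    return SNRVideo(frames=frames, median_image=med, noise_image=noise)


def preprocess_video(video: np.ndarray, neuron_masks=None,
                     kernel: CalciumKernel | None = None,
                     noise_quantiles=(0.25, 0.5)):
    """Full preprocessing: matched filter (if a kernel is derivable) + SNR.

    Returns (SNRVideo, CalciumKernel or None).  When neither a kernel nor
    labeled neuron masks are given, the SNR transform is applied directly.
    """
    video = np.asarray(video, dtype=np.float32)
    if kernel is None and neuron_masks is not None and len(neuron_masks):
        snippets = extract_transients(video, neuron_masks)
        if snippets:
            kernel = build_matched_kernel(snippets)
        else:
            warnings.warn("no transients found; skipping temporal filter", stacklevel=2)
    filtered = temporal_filter(video, kernel) if kernel is not None else video
    return snr_normalize(filtered, noise_quantiles), kernel
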