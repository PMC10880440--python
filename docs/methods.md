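# Methods

## Problem and model

Two-photon calcium imaging records neural activity as transient brightness
increases of calcium-indicator–expressing somas. Segmenting the *active* neurons
from a motion-corrected video `V ∈ R^{T×H×W}` is treated as per-frame semantic
segmentation followed by temporal consolidation. The pipeline assumes a
registered video, blob-like (roughly convex) somas that are optically resolvable
from their neighbours, and positive-going transients whose shape is approximately
a double exponential.

### SNR representation

Pixels are matched-filtered in time with the time-reversed mean transient of the
labeled neurons. Transient snippets are cut from mask-mean traces (converted to
SNR units per trace), keeping local maxima with peak SNR in [5, 8] whose peak is
the window maximum — mis-centred windows dominated by a neighbouring transient
would smear the average and reduce matched-filter gain. The average is truncated
where it falls below 5% of its peak, peak-normalized and reversed. Filtering is
correlation aligned so that a template-shaped transient peaks at its true peak
frame; boundaries are reflect-padded.

The SNR video is `(filtered − median)/noise` per pixel, with `noise =
(Q50 − Q25)/0.6745` (lower-sided quantile spread, floored at 1e-6). The lower
side is used because calcium transients are positive-going and would inflate an
upper-sided estimate. Quantiles use linear interpolation throughout. The
transform is invariant to per-pixel affine gain, so absolute detector gain does
not matter.

### Networks and losses

Three shallow U-Nets share a three-level encoder (4/8/16 channels, two 2×2
max-poolings, dropout 0.1/0.1/0.2 by depth) and differ in decoder width
(deepest-first 10/6, 12/8, 16/10), giving 4,443 / 5,277 / 6,797 trainable
parameters. Variant A is the final-prediction network. Inputs are reflect-padded
to multiples of 8 and outputs cropped back; the head is a 1×1 convolution with a
sigmoid. Exact decoder widths are a free design choice constrained to keep the
counts strictly ordered and below 10,000.

Supervised stages use `focal + 0.01·dice` (the 100:1 weighting; focal γ=2,
α=0.25 applied uniformly, dice smoothing 1 px to avoid 0/0 on empty frames);
pseudolabel training uses mean binary cross-entropy against soft targets.
Because no deep-learning framework is part of the dependency set and the
networks are tiny, layers, losses and Adam (lr 0.001, β=0.9/0.999) are
implemented directly on NumPy arrays with hand-derived gradients; a
finite-difference check in the test suite guards the backward pass.

### Training schedule

Defaults follow the published schedule: 200 supervised epochs for each ensemble
member, pseudolabels from up to 1,800 unlabeled frames (all remaining frames,
with a warning, when fewer exist), 25 BCE epochs, 200 fine-tuning epochs, with
random flips/rotations (the dihedral group of the square) applied identically to
frame and target. Each member sees an independent augmentation stream.
Pseudolabels are kept soft. A desk-scale profile (50/10/50 epochs, batch size 4)
is provided for experiments that must finish in minutes on one CPU; all reported
synthetic-scene numbers use it. All randomness derives from one integer seed via
named child streams, so reruns are bit-identical.

### Postprocessing

`binarize (strict >) → 8-connected components ≥ min_area → cross-frame merge →
consecutive-frame filter`. Merging is the exact transitive closure of pairwise
colocalization (union-find; a KD-tree on centroids prunes candidate pairs
losslessly, since any overlapping pair lies within twice the maximal component
radius). Two components are colocalized when COM distance < `centroid_dist`, or
IoU > 0.5, or consume ratio > 0.75. The consume ratio is evaluated against the
**larger** mask: with the smaller mask as reference, a single transient blob
bridging two co-active neighbouring somas consumes each soma's own components
entirely and transitive closure then fuses the pair permanently; the
larger-reference convention keeps merging conservative while the COM criterion
still gathers a neuron's partial detections. The convention is a keyword
argument. A record's final mask keeps pixels present in ≥ 50% of its member
components (union fallback), which suppresses per-frame flicker; records need
one run of ≥ `min_consecutive` consecutive active frames to survive.

### FLHO

Step 1 estimates `p_thresh` from labeled neurons active (mean in-mask SNR above
an activity threshold, default 3 SNR units, configurable) on labeled frames: per
neuron the median over active labeled frames of the per-frame median in-mask
probability; the 25th percentile of these medians is the intermediate threshold,
the median capped at 0.8 the final one. Step 2 grid-searches
`min_area` (default 30:10:150 px scaled by `(soma_radius/6)²`) ×
`centroid_dist` (2:1:10 px) for maximal frame-level F1 on the labeled frames at
the intermediate threshold; ties prefer smaller `centroid_dist` then larger
`min_area` (conservative merging and noise rejection). Steps 3–4 threshold *all*
frames at the final `p_thresh`, record each neuron's longest run of colocalized
detections, and set `min_consecutive` to the second-smallest nonzero run
(the minimum is often an outlier), capped at 8 frames. Frame-level F1 pools
TP/GT/Pred counts over frames rather than averaging per-frame F1, which is
stable when frames hold few neurons.

The single-model baseline used for comparisons tunes `p_thresh × min_area ×
centroid_dist` by the same labeled-frame grid search (ties prefer the lower
threshold, as a naive search does) and cannot estimate `min_consecutive` from
isolated random frames — it uses 1. This mirrors the known failure mode of naive
grid search in the few-label regime: underestimated `p_thresh` and admitted
false positives.

### Evaluation

Predictions match ground truth one-to-one greedily by descending IoU at a 0.5
threshold (configurable); a brute-force optimal-assignment oracle agrees with
the greedy matcher on ≥95% of random small instances. Mask quality is mask area
over rasterized convex-hull area (hull over pixel centers, boundary inclusive);
per-neuron peak SNR is the max over frames of mean in-mask SNR.

## Synthetic scenes

The generator emulates planar two-photon data: elliptical somas (random
orientation/eccentricity) with Bernoulli spikes per frame convolved with a
unit-peak kernel `(1 − e^{−t/rise})·e^{−t/decay}` (rise 2, decay 8 frames),
uniform per-event amplitudes, a smooth low-spatial-frequency neuropil field
modulated by a slow sinusoid, constant baseline and i.i.d. Gaussian noise. One
seed feeds per-neuron child streams, so scenes are reproducible independently of
placement order. Placement enforces a pairwise overlap cap (rejection sampling,
1,000 retries, capacity error naming the achievable count) and, by default, a
2 px somatic-exclusion gap between soma boundaries: cell bodies are optically
resolvable in the imaging regimes this method targets, and an 8-connectivity
postprocessor cannot, by construction, split two somas that touch. Setting
`min_soma_gap=0` restores contact/overlap up to the cap.

Preset study scenes are 64×64×1000 with 20 neurons of radius 2.5–3.5 px (~14%
soma coverage, comparable to cortical datasets; the first default of radius
3–5 px produced ~25% coverage, denser than any regime the method targets, and
was corrected). Transient amplitudes are calibrated once so the measured
post-filter peak SNR averages ≈10 ("easy") and ≈5 ("hard") at noise σ=1. Spike
rate 0.012/frame ≈ 0.4 Hz at 30 Hz imaging.

What the generator does **not** model: motion artifacts, dendrites/axons,
one-photon background, indicator nonlinearity/saturation, and correlated noise.
Passing tests therefore demonstrate correctness of the pipeline's mechanics and
its behaviour under the stated SNR regimes, not performance on real tissue.

## Numerical choices and limitations

- Probabilities are clipped to [1e-7, 1 − 1e-7] inside log losses; all losses
  are finite for any input.
- Strict inequality at `p_thresh`; 8-connectivity for components; 0-based
  (row, col)/frame indices everywhere.
- Reduced problem sizes for the bundled experiments (desk-scale schedule,
  64×64×1000 scenes, three seeds) are the package's chosen study sizes; the
  full-scale defaults remain the config defaults.
- Known limitations: overlapping/touching somas are fused by design of the
  connectivity-based postprocessing; neurons that never fire cannot be found;
  FLHO needs at least one labeled neuron active on a labeled frame (it raises a
  clear error otherwise); very long kernels relative to the video are rejected.
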