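"""Probability maps to unique neuron masks.

Four-stage chain controlled by four hyperparameters: binarize at ``p_thresh``
(strict inequality), drop connected components smaller than ``min_area``
(8-connectivity), merge colocalized components across frames into neuron
records (transitive closure over pairwise colocalization), and discard records
without a run of at least ``min_consecutive`` consecutive active frames.

Two components are colocalized when their centers of mass are closer than
``centroid_dist``, or IoU > 0.5, or the consume ratio (intersection over the
larger mask) exceeds 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

EIGHT_CONN = np.ones((3, 3), dtype=int)
IOU_MERGE = 0.5
CONSUME_MERGE = 0.75


@dataclass
class Hyperparams:
    """The four postprocessing hyperparameters."""

    p_thresh: float
    min_area: int
    centroid_dist: float
    min_consecutive: int

    def __post_init__(self):
        if not (0.0 < self.p_thresh <= 1.0):
            raise ValueError("p_thresh must lie in (0, 1]")
        if self.min_area < 1 or self.min_consecutive < 1:
            raise ValueError("min_area and min_consecutive must be >= 1")
        if self.centroid_dist < 0:
            raise ValueError("centroid_dist must be nonnegative")

    def to_dict(self) -> dict:
        return {"p_thresh": float(self.p_thresh), "min_area": int(self.min_area),
                "centroid_dist": float(self.centroid_dist),
                "min_consecutive": int(self.min_consecutive)}


@dataclass
class RoiComponent:
    """A single-frame 8-connected region of active pixels."""

    frame_index: int
    pixels: np.ndarray               # (K, 2) row/col coordinates
    shape: tuple                     # field (H, W)
    flat: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.flat is None:
            self.flat = np.sort(self.pixels[:, 0] * self.shape[1] + self.pixels[:, 1])

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))

    @property
    def radius(self) -> float:
        """Max distance from the centroid to any member pixel."""
        cy, cx = self.centroid
        d = np.hypot(self.pixels[:, 0] - cy, self.pixels[:, 1] - cx)
        return float(d.max()) if len(d) else 0.0

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @classmethod
    def from_mask(cls, mask: np.ndarray, frame_index: int = -1) -> "RoiComponent":
        pix = np.argwhere(np.asarray(mask, dtype=bool))
        if len(pix) == 0:
            raise ValueError("cannot build a component from an empty mask")
        return cls(frame_index=frame_index, pixels=pix, shape=mask.shape)


@dataclass
class NeuronRecord:
    """A temporally merged neuron: members, active frames, consolidated mask."""

    id: int
    member_components: list
    active_frames: list              # sorted unique frame indices
    final_mask: np.ndarray           # (H, W) bool
    flat: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.flat is None:
            self.flat = np.flatnonzero(self.final_mask.ravel())

    @property
    def centroid(self) -> tuple:
        pix = np.argwhere(self.final_mask)
        return (float(pix[:, 0].mean()), float(pix[:, 1].mean()))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def binarize(prob_map: np.ndarray, p_thresh: float) -> np.ndarray:
    """Active iff value > p_thresh (strict)."""
    if not (0.0 < p_thresh <= 1.0):
        raise ValueError("p_thresh must lie in (0, 1]")
    return np.asarray(prob_map) > p_thresh


def extract_components(binary_frame: np.ndarray, min_area: int,
                       frame_index: int = 0) -> list:
    """8-connected components with area >= min_area."""
    lab, n = ndimage.label(np.asarray(binary_frame, dtype=bool), structure=EIGHT_CONN)
    comps = []
    if n == 0:
        return comps
    shape = binary_frame.shape
    objects = ndimage.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        sub = np.argwhere(lab[sl] == i)
        if len(sub) < min_area:
            continue
        pix = sub + np.array([s.start for s in sl])
        comps.append(RoiComponent(frame_index=frame_index, pixels=pix, shape=shape))
    return comps


def iou(m1: np.ndarray, m2: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(m1, m2).sum()
    if union == 0:
        warnings.warn("IoU of two empty masks is undefined; returning 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(m1, m2).sum() / union)


def consume(m1: np.ndarray, m2: np.ndarray) -> float:
    """Fraction of m2 covered by m1: |m1 & m2| / |m2|."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("masks must share a shape")
    a2 = m2.sum()
    if a2 == 0:
        raise ValueError("consume is undefined for an empty m2")
    return float(np.logical_and(m1, m2).sum() / a2)


def _flat_of(obj) -> np.ndarray:
    return obj.flat


def _centroid_of(obj) -> tuple:
    return obj.centroid


def components_colocalized(a, b, centroid_dist: float,
                           consume_denominator: str = "larger") -> bool:
    """COM distance < centroid_dist, or IoU > 0.5, or consume ratio > 0.75.

    ``a`` may be a RoiComponent or NeuronRecord; ``b`` a RoiComponent.  The
    consume ratio is evaluated with the ``consume_denominator`` mask ("larger"
    by default) as the reference m2.  The larger-denominator convention is
    deliberately conservative: with the smaller mask as reference, any
    transient two-neuron blob bridging adjacent somas consumes each soma's
    own components completely and transitive merging then fuses the pair
    into one record.
    """
    ca, cb = _centroid_of(a), _centroid_of(b)
    if np.hypot(ca[0] - cb[0], ca[1] - cb[1]) < centroid_dist:
        return True
    fa, fb = _flat_of(a), _flat_of(b)
    inter = np.intersect1d(fa, fb, assume_unique=True).size
    if inter == 0:
        return False
    union = fa.size + fb.size - inter
    if inter / union > IOU_MERGE:
        return True
    if consume_denominator == "larger":
        denom = max(fa.size, fb.size)
    elif consume_denominator == "smaller":
        denom = min(fa.size, fb.size)
    else:
        raise ValueError("consume_denominator must be 'larger' or 'smaller'")
    return inter / denom > CONSUME_MERGE


# ---------------------------------------------------------------------------
# cross-frame merging (exact pairwise transitive closure)
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _candidate_pairs(components, centroid_dist):
    """All pairs that could possibly colocalize (lossless KD-tree pruning).

    Overlapping components have COM distance <= r_i + r_j <= 2*max_radius, so a
    radius of max(centroid_dist, 2*max_radius) misses no colocalized pair.
    """
    centroids = np.array([c.centroid for c in components])
    max_r = max((c.radius for c in components), default=0.0)
    radius = max(centroid_dist, 2.0 * max_r) + 1e-9
    tree = cKDTree(centroids)
    return tree.query_pairs(radius, output_type="ndarray")


def merge_components(components: list, centroid_dist: float) -> list:
    """Merge colocalized components across frames into NeuronRecords.

    Records are the transitive closure of the pairwise colocalization
    relation; the result is independent of input ordering up to id labels.
    """
    if not components:
        return []
    order = np.lexsort((
        [c.centroid[1] for c in components],
        [c.centroid[0] for c in components],
        [c.frame_index for c in components],
    ))
    comps = [components[i] for i in order]
    uf = _UnionFind(len(comps))
    pairs = _candidate_pairs(comps, centroid_dist)
    # sort pairs for determinism; same-set pairs are skipped without mask work
    for i, j in sorted(map(tuple, pairs)):
        if uf.find(i) == uf.find(j):
            continue
        if components_colocalized(comps[i], comps[j], centroid_dist):
            uf.union(i, j)

    groups = {}
    for i, c in enumerate(comps):
        groups.setdefault(uf.find(i), []).append(c)

    records = []
    shape = comps[0].shape
    for rid, (_, members) in enumerate(sorted(groups.items())):
        counts = np.zeros(shape[0] * shape[1], dtype=np.int32)
        for m in members:
            counts[m.flat] += 1
        majority = counts * 2 >= len(members)  # pixel in >= 50% of members
        final = majority if majority.any() else counts > 0
        frames = sorted({m.frame_index for m in members})
        records.append(NeuronRecord(id=rid, member_components=members,
                                    active_frames=frames,
                                    final_mask=final.reshape(shape)))
    return records


def max_consecutive_run(frames) -> int:
    """Length of the longest run of consecutive integers in a sorted set."""
    frames = sorted(set(int(f) for f in frames))
    if not frames:
        return 0
    best = cur = 1
    for a, b in zip(frames, frames[1:]):
        cur = cur + 1 if b == a + 1 else 1
        best = max(best, cur)
    return best


def filter_consecutive(records: list, min_consecutive: int) -> list:
    """Keep records with a run of >= min_consecutive consecutive active frames."""
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    kept = [r for r in records
            if max_consecutive_run(r.active_frames) >= min_consecutive]
    for new_id, r in enumerate(kept):
        r.id = new_id
    return kept


def postprocess(prob_maps: np.ndarray, hp: Hyperparams) -> list:
    """binarize -> extract_components -> merge_components -> filter_consecutive."""
    components = []
    for t, frame in enumerate(np.asarray(prob_maps)):
        components.extend(
            extract_components(binarize(frame, hp.p_thresh), hp.min_area, t))
    records = merge_components(components, hp.centroid_dist)
    return filter_consecutive(records, hp.min_consecutive)
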