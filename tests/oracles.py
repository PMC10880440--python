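"""Independent brute-force references used to cross-check the implementation.

These deliberately avoid the library's own union-find / KD-tree / greedy code
paths: merging is checked against explicit all-pairs transitive closure via
graph reachability, and mask matching against exhaustive optimal assignment.
"""

from itertools import combinations, permutations

import networkx as nx
import numpy as np

from sand2p.postprocess import (binarize, extract_components,
                                components_colocalized, max_consecutive_run)


def brute_force_postprocess(prob_maps, hp):
    """Reference pipeline: full pairwise closure via networkx components.

    Returns a set of frozensets; each inner frozenset is one merged record's
    member components encoded as (frame, sorted pixel tuple).
    """
    comps = []
    for t, frame in enumerate(np.asarray(prob_maps)):
        comps.extend(extract_components(binarize(frame, hp.p_thresh), hp.min_area, t))
    g = nx.Graph()
    g.add_nodes_from(range(len(comps)))
    for i, j in combinations(range(len(comps)), 2):
        if components_colocalized(comps[i], comps[j], hp.centroid_dist):
            g.add_edge(i, j)
    groups = []
    for cc in nx.connected_components(g):
        members = [comps[i] for i in cc]
        frames = {m.frame_index for m in members}
        if max_consecutive_run(frames) < hp.min_consecutive:
            continue
        groups.append(frozenset((m.frame_index, tuple(map(tuple, sorted(map(tuple, m.pixels)))))
                                for m in members))
    return set(groups)


def record_signature(records):
    """Encode library output records in the oracle's id-free representation."""
    return {
        frozenset((m.frame_index, tuple(map(tuple, sorted(map(tuple, m.pixels)))))
                  for m in r.member_components)
        for r in records
    }


def optimal_assignment_tp(pred, gt, iou_threshold):
    """Max number of one-to-one matches with IoU >= threshold, by enumeration."""
    pred = [np.asarray(p, bool) for p in pred]
    gt = [np.asarray(g, bool) for g in gt]
    iou = np.zeros((len(pred), len(gt)))
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            u = np.logical_or(p, g).sum()
            iou[i, j] = np.logical_and(p, g).sum() / u if u else 0.0
    ok = iou >= iou_threshold
    n, m = len(pred), len(gt)
    if n == 0 or m == 0:
        return 0
    best = 0
    idx = list(range(m)) + [-1] * max(0, n - m)
    for perm in set(permutations(idx, n)):
        tp = sum(1 for i, j in enumerate(perm) if j >= 0 and ok[i, j])
        best = max(best, tp)
    return best


def random_blob_stack(rng, shape=(30, 16, 16), max_blobs=4):
    """Probability-map stack with a few planted Gaussian-ish blobs."""
    T, H, W = shape
    maps = rng.uniform(0.0, 0.25, size=shape)
    n_blobs = rng.integers(1, max_blobs + 1)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(2, H - 3), rng.uniform(2, W - 3)
        r = rng.uniform(1.2, 2.5)
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r * r))
        t0 = rng.integers(0, T - 5)
        dur = rng.integers(2, 12)
        for t in range(t0, min(T, t0 + dur)):
            maps[t] = np.maximum(maps[t], 0.95 * blob * rng.uniform(0.7, 1.0))
    return maps.astype(np.float32)
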