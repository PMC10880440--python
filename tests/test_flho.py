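import numpy as np
import pytest

from sand2p.evaluate import frame_f1
from sand2p.flho import (EstimationError, GridSpec, default_grid,
                         estimate_min_consecutive, estimate_p_thresh,
                         grid_search_spatial, max_consecutive_per_neuron,
                         neuron_active_frames, probability_distribution, run_flho)
from sand2p.postprocess import binarize, extract_components, merge_components


class FakeSNR:
    def __init__(self, frames):
        self.frames = np.asarray(frames, dtype=np.float32)


def square_mask(r0, c0, size, shape=(16, 16)):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + size, c0:c0 + size] = True
    return m


class TestActiveFrames:
    def test_constructed_trace_thresholding(self):
        mask = square_mask(4, 4, 3)
        frames = np.zeros((6, 16, 16), dtype=np.float32)
        frames[3][mask] = 5.0
        frames[4][mask] = 5.0
        active = neuron_active_frames(FakeSNR(frames), [mask], 3.0)
        assert active[0] == {3, 4}

    def test_threshold_below_minimum_activates_all(self):
        frames = np.zeros((5, 16, 16), dtype=np.float32)
        active = neuron_active_frames(FakeSNR(frames), [square_mask(2, 2, 3)], -1.0)
        assert active[0] == set(range(5))

    def test_silent_neuron_warns_and_is_empty(self):
        frames = np.zeros((5, 16, 16), dtype=np.float32)
        with pytest.warns(UserWarning, match="silent"):
            active = neuron_active_frames(FakeSNR(frames), [square_mask(2, 2, 3)], 3.0)
        assert active[0] == set()


class TestProbabilityDistribution:
    def test_constant_map_inside_mask(self):
        mask = square_mask(4, 4, 3)
        maps = np.zeros((1, 16, 16), dtype=np.float32)
        maps[0][mask] = 0.7
        stats = probability_distribution(maps, [5], [mask], [{5}])
        assert stats[0].median_probability == pytest.approx(0.7)

    def test_frame_median_of_three_values(self):
        mask = np.zeros((4, 4), bool)
        mask[0, :3] = True
        maps = np.zeros((1, 4, 4), dtype=np.float32)
        maps[0, 0, :3] = [0.2, 0.4, 0.9]
        stats = probability_distribution(maps, [0], [mask], [{0}])
        assert stats[0].median_probability == pytest.approx(0.4)

    def test_neuron_median_interpolates_two_frames(self):
        mask = square_mask(1, 1, 2, shape=(6, 6))
        maps = np.zeros((2, 6, 6), dtype=np.float32)
        maps[0][mask] = 0.6
        maps[1][mask] = 0.8
        stats = probability_distribution(maps, [0, 1], [mask], [{0, 1}])
        assert stats[0].median_probability == pytest.approx(0.7)

    def test_inactive_neurons_excluded_and_error_when_none(self):
        mask = square_mask(1, 1, 2, shape=(6, 6))
        maps = np.zeros((1, 6, 6), dtype=np.float32)
        with pytest.raises(EstimationError):
            probability_distribution(maps, [0], [mask], [set()])


class TestPThresh:
    def test_interpolated_percentiles_of_five(self):
        stats = [type("S", (), {"median_probability": v})()
                 for v in (0.5, 0.6, 0.7, 0.8, 0.9)]
        inter, final = estimate_p_thresh(stats)
        assert inter == pytest.approx(0.6)
        assert final == pytest.approx(0.7)

    def test_final_capped_at_80_percent(self):
        stats = [type("S", (), {"median_probability": 0.95})() for _ in range(4)]
        _, final = estimate_p_thresh(stats)
        assert final == 0.8

    def test_single_value_used_for_both(self):
        stats = [type("S", (), {"median_probability": 0.6})()]
        inter, final = estimate_p_thresh(stats)
        assert inter == pytest.approx(0.6) and final == pytest.approx(0.6)

    def test_intermediate_never_exceeds_uncapped_median(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(0, 1, size=rng.integers(1, 9))
            stats = [type("S", (), {"median_probability": v})() for v in vals]
            inter, _ = estimate_p_thresh(stats)
            assert inter <= np.median(vals) + 1e-12


class TestGridSearch:
    def test_grid_spec_validation(self):
        with pytest.raises(ValueError):
            GridSpec(min_area_values=[], centroid_dist_values=[2])
        with pytest.raises(ValueError):
            GridSpec(min_area_values=[3, 2], centroid_dist_values=[2])

    def test_singleton_grid_returned(self):
        mask = square_mask(4, 4, 4)
        maps = np.zeros((2, 16, 16), dtype=np.float32)
        maps[:, mask] = 0.9
        grid = GridSpec(min_area_values=[3], centroid_dist_values=[2])
        (area, dist), _ = grid_search_spatial(maps, [[mask], [mask]], 0.5, grid)
        assert (area, dist) == (3, 2)

    def test_maximizer_agrees_with_independent_re_evaluation(self):
        rng = np.random.default_rng(1)
        masks = [square_mask(2, 2, 4), square_mask(9, 9, 4)]
        maps = rng.uniform(0, 0.4, size=(3, 16, 16)).astype(np.float32)
        for m in masks:
            maps[:2][:, m] = 0.9
        gt = [[masks[0], masks[1]], [masks[0], masks[1]], []]
        grid = GridSpec(min_area_values=[2, 6, 12], centroid_dist_values=[2, 4])
        (area, dist), table = grid_search_spatial(maps, gt, 0.5, grid)
        # recompute every cell independently
        for ai, a in enumerate(grid.min_area_values):
            for di, d in enumerate(grid.centroid_dist_values):
                comps = []
                for t, fr in enumerate(maps):
                    comps.extend(extract_components(binarize(fr, 0.5), a, t))
                recs = merge_components(comps, d)
                preds = [[] for _ in range(3)]
                for r in recs:
                    for f in r.active_frames:
                        preds[f].append(r.final_mask)
                try:
                    f1 = frame_f1(preds, gt, 0.5)
                except ValueError:
                    f1 = 0.0
                assert table[ai, di] == pytest.approx(f1)
        assert table[np.argwhere(np.array(grid.min_area_values) == area)[0, 0],
                     np.argwhere(np.array(grid.centroid_dist_values) == dist)[0, 0]] \
            == pytest.approx(table.max())

    def test_noise_blobs_push_min_area_up(self):
        # speckle components of area < 4 are pure noise; the chosen min_area
        # must remove them
        rng = np.random.default_rng(2)
        mask = square_mask(5, 5, 5)
        maps = np.zeros((4, 16, 16), dtype=np.float32)
        maps[:, mask] = 0.9
        for t in range(4):
            for _ in range(6):
                r, c = rng.integers(0, 15, 2)
                if not mask[r, c]:
                    maps[t, r, c] = 0.9
        grid = GridSpec(min_area_values=[1, 4, 9], centroid_dist_values=[2])
        (area, _), _ = grid_search_spatial(maps, [[mask]] * 4, 0.5, grid)
        assert area >= 4


class TestMinConsecutive:
    def test_run_lengths_from_detections(self):
        mask = square_mask(4, 4, 4)
        maps = np.zeros((10, 16, 16), dtype=np.float32)
        for t in (1, 2, 3, 7, 8):
            maps[t][mask] = 0.9
        counts = max_consecutive_per_neuron(maps, 0.5, 2, [mask], 3.0)
        assert counts[0] == 3

    def test_undetected_neuron_counts_zero(self):
        maps = np.zeros((5, 16, 16), dtype=np.float32)
        counts = max_consecutive_per_neuron(maps, 0.5, 2, [square_mask(4, 4, 3)], 3.0)
        assert counts[0] == 0

    def test_always_detected_counts_t(self):
        mask = square_mask(4, 4, 4)
        maps = np.zeros((6, 16, 16), dtype=np.float32)
        maps[:, mask] = 0.9
        counts = max_consecutive_per_neuron(maps, 0.5, 2, [mask], 3.0)
        assert counts[0] == 6

    def test_second_smallest_rule(self):
        assert estimate_min_consecutive([2, 5, 7]) == 5

    def test_cap_at_eight(self):
        assert estimate_min_consecutive([9, 10, 12]) == 8

    def test_single_count_fallback(self):
        assert estimate_min_consecutive([4]) == 4

    def test_zeros_dropped_before_rule(self):
        assert estimate_min_consecutive([0, 0, 2, 5]) == 5

    def test_all_zero_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert estimate_min_consecutive([0, 0]) == 1


class TestRunFLHO:
    def make_planted(self, p_values):
        """Scene with one square neuron per planted in-mask probability."""
        n = len(p_values)
        shape = (16 * n, 16)
        masks = [square_mask(16 * i + 5, 5, 4, shape) for i in range(n)]
        T = 30
        frames = np.zeros((T,) + shape, dtype=np.float32)
        maps = np.zeros((T,) + shape, dtype=np.float32)
        labeled = [3, 4, 5, 6]
        for i, (m, p) in enumerate(zip(masks, p_values)):
            frames[2:10, m] = 6.0            # active on frames 2..9
            maps[2:10, m] = p
        return FakeSNR(frames), maps, labeled, masks

    def test_planted_medians_recovered_exactly(self):
        p_star = [0.55, 0.65, 0.75]
        snr, maps, labeled, masks = self.make_planted(p_star)
        grid = GridSpec(min_area_values=[2, 4], centroid_dist_values=[2, 4])
        hp = run_flho(snr, maps, labeled, masks, grid, activity_thresh=3.0)
        assert hp.p_thresh == pytest.approx(np.median(p_star))

    def test_high_medians_capped(self):
        snr, maps, labeled, masks = self.make_planted([0.95, 0.97, 0.99])
        grid = GridSpec(min_area_values=[2], centroid_dist_values=[2])
        hp = run_flho(snr, maps, labeled, masks, grid, activity_thresh=3.0)
        assert hp.p_thresh == 0.8

    def test_output_respects_caps_and_is_deterministic(self):
        snr, maps, labeled, masks = self.make_planted([0.6, 0.7, 0.8])
        grid = default_grid(soma_radius=2.0)
        hp1 = run_flho(snr, maps, labeled, masks, grid, activity_thresh=3.0)
        hp2 = run_flho(snr, maps, labeled, masks, grid, activity_thresh=3.0)
        assert hp1 == hp2
        assert hp1.p_thresh <= 0.8 and hp1.min_consecutive <= 8

    def test_intermediate_at_most_final_before_cap(self):
        snr, maps, labeled, masks = self.make_planted([0.5, 0.6, 0.7, 0.8])
        maps_labeled = maps[np.asarray(labeled)]
        active = neuron_active_frames(snr, masks, 3.0)
        stats = probability_distribution(maps_labeled, labeled, masks, active)
        inter, final = estimate_p_thresh(stats)
        assert inter <= np.median([s.median_probability for s in stats])
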