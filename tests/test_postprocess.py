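import numpy as np
import pytest

from oracles import brute_force_postprocess, random_blob_stack, record_signature
from sand2p.postprocess import (Hyperparams, RoiComponent, binarize,
                                components_colocalized, consume,
                                extract_components, filter_consecutive, iou,
                                max_consecutive_run, merge_components, postprocess)


def mask_of(coords, shape=(8, 8)):
    m = np.zeros(shape, dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return m


def comp_of(coords, frame=0, shape=(16, 16)):
    return RoiComponent(frame_index=frame, pixels=np.array(coords), shape=shape)


class TestBinarize:
    def test_all_above_threshold(self):
        assert binarize(np.full((3, 3), 0.9), 0.5).all()

    def test_none_above_threshold(self):
        assert not binarize(np.full((3, 3), 0.3), 0.5).any()

    def test_strict_inequality_at_threshold(self):
        assert not binarize(np.array([[0.5]]), 0.5)[0, 0]

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.1])
    def test_out_of_range_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), bad)


class TestExtractComponents:
    def test_empty_frame(self):
        assert extract_components(np.zeros((5, 5), bool), 1) == []

    def test_diagonal_pixels_are_one_component(self):
        frame = mask_of([(1, 1), (2, 2)])
        comps = extract_components(frame, 1)
        assert len(comps) == 1 and comps[0].area == 2

    def test_min_area_removal(self):
        frame = mask_of([(0, 0), (0, 1), (0, 2)])
        assert extract_components(frame, 4) == []
        assert len(extract_components(frame, 3)) == 1

    def test_centroid_is_unweighted_pixel_mean(self):
        comps = extract_components(mask_of([(2, 2), (2, 3), (3, 2), (3, 3)]), 1)
        assert comps[0].centroid == (2.5, 2.5)


class TestIoUConsume:
    def test_identical_masks(self):
        m = mask_of([(1, 1), (1, 2)])
        assert iou(m, m) == 1.0
        assert consume(m, m) == 1.0

    def test_disjoint_masks(self):
        m1, m2 = mask_of([(0, 0)]), mask_of([(5, 5)])
        assert iou(m1, m2) == 0.0
        assert consume(m1, m2) == 0.0

    def test_partial_overlap_counts(self):
        m1 = mask_of([(0, 0), (0, 1), (0, 2)])
        m2 = mask_of([(0, 2), (0, 3)])
        assert iou(m1, m2) == pytest.approx(1 / 4)

    def test_subset_consumed_fully(self):
        m1 = mask_of([(0, 0), (0, 1), (0, 2)])
        m2 = mask_of([(0, 1)])
        assert consume(m1, m2) == 1.0

    def test_consume_boundary_three_quarters(self):
        m2 = mask_of([(0, 0), (0, 1), (0, 2), (0, 3)])
        m1 = mask_of([(0, 0), (0, 1), (0, 2), (1, 0)])
        assert consume(m1, m2) == pytest.approx(0.75)

    def test_both_empty_iou_warns_zero(self):
        with pytest.warns(UserWarning):
            assert iou(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 0.0

    def test_empty_reference_consume_rejected(self):
        with pytest.raises(ValueError):
            consume(mask_of([(0, 0)]), np.zeros((8, 8), bool))

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1 = rng.random((6, 6)) < 0.4
            m2 = rng.random((6, 6)) < 0.4
            if not (m1.any() and m2.any()):
                continue
            assert iou(m1, m2) == iou(m2, m1)
            assert iou(m1, m2) <= consume(m1, m2) + 1e-12
            assert iou(m1, m2) <= consume(m2, m1) + 1e-12


class TestColocalization:
    def test_identical_components_colocalized(self):
        a = comp_of([(2, 2), (2, 3)])
        assert components_colocalized(a, comp_of([(2, 2), (2, 3)], frame=5), 0.0)

    def test_distant_small_components_not_colocalized(self):
        assert not components_colocalized(comp_of([(1, 1)]),
                                          comp_of([(12, 12)]), 2.0)

    def test_centroid_distance_branch(self):
        a = comp_of([(4, 4)])
        b = comp_of([(4, 5)])  # COM distance 1, zero overlap
        assert components_colocalized(a, b, 2.0)
        assert not components_colocalized(a, b, 1.0)


class TestMerge:
    def test_identical_component_across_frames_single_record(self):
        comps = [comp_of([(3, 3), (3, 4)], frame=f) for f in (1, 2, 3)]
        records = merge_components(comps, 2.0)
        assert len(records) == 1
        assert records[0].active_frames == [1, 2, 3]

    def test_unrelated_components_stay_separate(self):
        comps = [comp_of([(1, 1)], frame=0), comp_of([(12, 12)], frame=1)]
        assert len(merge_components(comps, 2.0)) == 2

    def test_transitive_chain_merges(self):
        a = comp_of([(4, c) for c in range(0, 4)], frame=0)
        b = comp_of([(4, c) for c in range(2, 7)], frame=1)   # near a and c
        c = comp_of([(4, c) for c in range(5, 9)], frame=2)
        assert not components_colocalized(a, c, 3.0)
        assert components_colocalized(a, b, 3.0)
        assert components_colocalized(b, c, 3.0)
        records = merge_components([a, b, c], 3.0)
        assert len(records) == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        maps = random_blob_stack(rng, shape=(10, 16, 16))
        comps = []
        for t, fr in enumerate(maps):
            comps.extend(extract_components(binarize(fr, 0.5), 2, t))
        ref = record_signature(merge_components(comps, 3.0))
        perm = [comps[i] for i in rng.permutation(len(comps))]
        assert record_signature(merge_components(perm, 3.0)) == ref

    def test_majority_final_mask(self):
        big = [(3, 3), (3, 4), (4, 3), (4, 4)]
        comps = [comp_of(big, frame=f) for f in (0, 1, 2)]
        comps.append(comp_of(big + [(5, 5)], frame=3))  # flicker pixel
        rec = merge_components(comps, 2.0)[0]
        assert rec.final_mask[3, 3] and not rec.final_mask[5, 5]


class TestConsecutiveFilter:
    def test_run_of_three_kept(self):
        rec = merge_components([comp_of([(2, 2)], frame=f) for f in (1, 2, 3)], 1.0)
        assert len(filter_consecutive(rec, 3)) == 1

    def test_gappy_activity_removed(self):
        rec = merge_components([comp_of([(2, 2)], frame=f) for f in (1, 3, 5)], 1.0)
        assert filter_consecutive(rec, 2) == []

    def test_min_one_keeps_everything(self):
        rec = merge_components([comp_of([(2, 2)], frame=9)], 1.0)
        assert len(filter_consecutive(rec, 1)) == 1

    def test_run_length_helper(self):
        assert max_consecutive_run([1, 2, 3, 7, 8]) == 3
        assert max_consecutive_run([]) == 0
        assert max_consecutive_run([4]) == 1


class TestHyperparams:
    @pytest.mark.parametrize("bad", [dict(p_thresh=0.0), dict(p_thresh=1.2),
                                     dict(min_area=0), dict(min_consecutive=0),
                                     dict(centroid_dist=-1.0)])
    def test_invalid_hyperparams_rejected(self, bad):
        good = dict(p_thresh=0.5, min_area=2, centroid_dist=2.0, min_consecutive=1)
        good.update(bad)
        with pytest.raises(ValueError):
            Hyperparams(**good)


class TestPostprocessPipeline:
    def test_all_zero_maps_yield_no_neurons(self):
        hp = Hyperparams(p_thresh=0.5, min_area=1, centroid_dist=2.0,
                         min_consecutive=1)
        assert postprocess(np.zeros((10, 8, 8)), hp) == []

    def test_single_planted_neuron_recovered(self):
        maps = np.zeros((20, 16, 16), dtype=np.float32)
        fp = mask_of([(r, c) for r in range(5, 9) for c in range(5, 9)], (16, 16))
        maps[4:12, fp] = 0.9
        hp = Hyperparams(p_thresh=0.5, min_area=3, centroid_dist=3.0,
                         min_consecutive=5)
        records = postprocess(maps, hp)
        assert len(records) == 1
        assert iou(records[0].final_mask, fp) > 0.5
        assert records[0].active_frames == list(range(4, 12))

    def test_matches_brute_force_reference_on_random_stacks(self):
        rng = np.random.default_rng(42)
        hp = Hyperparams(p_thresh=0.5, min_area=2, centroid_dist=3.0,
                         min_consecutive=2)
        for _ in range(20):
            maps = random_blob_stack(rng)
            got = record_signature(postprocess(maps, hp))
            want = brute_force_postprocess(maps, hp)
            assert got == want

    def test_monotonicity_in_all_three_hyperparameters(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            maps = random_blob_stack(rng)
            # active pixels never increase with p_thresh
            for t in range(maps.shape[0]):
                low = binarize(maps[t], 0.4).sum()
                high = binarize(maps[t], 0.6).sum()
                assert high <= low
            # component count never increases with min_area
            frame = binarize(maps[5], 0.4)
            n_small = len(extract_components(frame, 1))
            n_large = len(extract_components(frame, 5))
            assert n_large <= n_small
            # final neuron count never increases with min_consecutive
            counts = []
            for mc in (1, 3, 6):
                hp = Hyperparams(p_thresh=0.5, min_area=2, centroid_dist=3.0,
                                 min_consecutive=mc)
                counts.append(len(postprocess(maps, hp)))
            assert counts[0] >= counts[1] >= counts[2]
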