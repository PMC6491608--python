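import numpy as np
import pytest

from lobuseg import (
    BinaryMask,
    ImageVolume,
    LabelVolume,
    PreprocessParams,
    SegmentationParams,
    apply_foreground,
    contact_ratio,
    distance_map,
    extract_seeds,
    gradient_magnitude,
    merge_subunits,
    segment_lobules,
    watershed_flood,
)
from lobuseg.types import (
    ConsistencyError,
    DegenerateHistogramError,
    DimensionalityError,
    EmptySLAError,
    MissingLabelError,
    NoSeedError,
    ParameterError,
)

import oracles


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(data=np.asarray(data, dtype=bool), spacing=spacing)


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def _labels(data, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(data=np.asarray(data, dtype=int), spacing=spacing)


class TestDistanceMap:
    def test_all_background_is_zero(self):
        out = distance_map(_mask(np.zeros((4, 4, 4))))
        assert not out.data.any()

    def test_single_foreground_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        out = distance_map(_mask(m))
        assert out.data[2, 2, 2] == pytest.approx(1.0)

    def test_cube_center_distance(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        out = distance_map(_mask(m))
        assert out.data[3, 3, 3] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_anisotropic(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 9, size=3))
        m = rng.random(shape) > 0.4
        spacing = tuple(rng.uniform(0.5, 3.0, size=3))
        out = distance_map(_mask(m, spacing))
        expected = oracles.brute_distance_map(m, spacing)
        assert np.allclose(out.data, expected)


class TestGradientMagnitude:
    def test_constant_volume_is_zero(self):
        out = gradient_magnitude(_vol(np.full((4, 4, 4), 9.0)))
        assert np.allclose(out.data, 0.0)

    def test_step_response_localized_at_interface(self):
        data = np.zeros((8, 5, 5))
        data[4:] = 1.0
        out = gradient_magnitude(_vol(data))
        for voxel in [(3, 2, 2), (4, 2, 2), (1, 2, 2), (7, 2, 2)]:
            assert out.data[voxel] == pytest.approx(
                oracles.brute_gradient_magnitude_at(data, voxel)
            )
        assert out.data[1, 2, 2] == 0.0
        assert out.data[3, 2, 2] > 0

    def test_linear_ramp_has_constant_interior_magnitude(self):
        x = np.arange(10, dtype=float)
        data = np.broadcast_to(x[:, None, None], (10, 6, 6)).copy()
        out = gradient_magnitude(_vol(data))
        interior = out.data[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, interior[0, 0, 0])
        assert interior[0, 0, 0] == pytest.approx(
            oracles.brute_gradient_magnitude_at(data, (5, 3, 3))
        )

    def test_thin_dimension_rejected(self):
        with pytest.raises(DimensionalityError):
            gradient_magnitude(_vol(np.zeros((5, 5, 2))))


class TestExtractSeeds:
    def test_two_separated_cubes_give_two_seeds(self):
        m = np.zeros((20, 7, 7), bool)
        m[1:4, 2:5, 2:5] = True
        m[14:17, 2:5, 2:5] = True
        dist = distance_map(_mask(m))
        seeds = extract_seeds(
            dist, SegmentationParams(distance_threshold=0.5, min_seed_voxels=1)
        )
        assert seeds.labels().size == 2

    def test_threshold_above_max_raises(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        dist = distance_map(_mask(m))
        with pytest.raises(NoSeedError):
            extract_seeds(dist, SegmentationParams(distance_threshold=10.0))

    def test_diagonal_voxels_split_by_connectivity(self):
        dist = _vol(np.zeros((4, 4, 4)))
        dist.data[1, 1, 1] = 5.0
        dist.data[2, 2, 2] = 5.0
        for conn, expected in [(26, 1), (6, 2)]:
            seeds = extract_seeds(
                dist,
                SegmentationParams(
                    distance_threshold=1.0, seed_connectivity=conn, min_seed_voxels=1
                ),
            )
            assert seeds.labels().size == expected

    def test_small_components_dropped(self):
        dist = _vol(np.zeros((10, 4, 4)))
        dist.data[1, 1, 1] = 5.0  # single voxel
        dist.data[5:8, 1:3, 1:3] = 5.0  # 12 voxels
        seeds = extract_seeds(
            dist, SegmentationParams(distance_threshold=1.0, min_seed_voxels=4)
        )
        assert seeds.labels().size == 1
        assert (seeds.data[5:8] > 0).any()

    def test_labels_numbered_in_scan_order(self):
        dist = _vol(np.zeros((9, 3, 3)))
        dist.data[1, 1, 1] = 5.0
        dist.data[4, 1, 1] = 5.0
        dist.data[7, 1, 1] = 5.0
        seeds = extract_seeds(
            dist, SegmentationParams(distance_threshold=1.0, min_seed_voxels=1)
        )
        assert seeds.data[1, 1, 1] == 1
        assert seeds.data[4, 1, 1] == 2
        assert seeds.data[7, 1, 1] == 3


class TestWatershedFlood:
    def test_single_seed_floods_connected_mask(self):
        m = np.ones((4, 4, 4), bool)
        seeds = np.zeros((4, 4, 4), int)
        seeds[0, 0, 0] = 1
        out = watershed_flood(_vol(np.zeros((4, 4, 4))), _labels(seeds), _mask(m))
        assert (out.data == 1).all()

    def test_1d_ridge_split_with_tie_rule(self):
        relief = np.array([0.0, 1.0, 2.0, 1.0, 0.0]).reshape(5, 1, 1)
        seeds = np.zeros((5, 1, 1), int)
        seeds[0], seeds[4] = 1, 2
        out = watershed_flood(_vol(relief), _labels(seeds), _mask(np.ones((5, 1, 1))))
        # fronts climb both slopes; the ridge voxel falls to label 1 by the
        # (relief, index, label) ordering
        assert out.data.ravel().tolist() == [1, 1, 1, 2, 2]

    def test_empty_mask_leaves_all_background(self):
        seeds = np.zeros((3, 3, 3), int)
        out = watershed_flood(
            _vol(np.zeros((3, 3, 3))), _labels(seeds), _mask(np.zeros((3, 3, 3)))
        )
        assert not out.data.any()

    def test_seed_outside_mask_rejected(self):
        seeds = np.zeros((3, 3, 3), int)
        seeds[0, 0, 0] = 1
        with pytest.raises(ConsistencyError):
            watershed_flood(
                _vol(np.zeros((3, 3, 3))), _labels(seeds), _mask(np.zeros((3, 3, 3)))
            )

    def test_unreachable_masked_voxels_stay_zero(self):
        m = np.zeros((7, 1, 1), bool)
        m[0:2] = True
        m[4:7] = True  # disconnected from the seeded part
        seeds = np.zeros((7, 1, 1), int)
        seeds[0] = 1
        out = watershed_flood(_vol(np.zeros((7, 1, 1))), _labels(seeds), _mask(m))
        assert out.data[0:2].tolist() == [[[1]], [[1]]]
        assert not out.data[4:7].any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scan_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, size=3))
        relief = rng.integers(0, 4, size=shape).astype(float)
        mask = rng.random(shape) > 0.25
        n_seeds = int(rng.integers(1, 4))
        seeds = np.zeros(shape, int)
        masked = np.argwhere(mask)
        if masked.size == 0:
            mask[0, 0, 0] = True
            masked = np.argwhere(mask)
        for lab, pick in enumerate(
            rng.choice(len(masked), size=min(n_seeds, len(masked)), replace=False),
            start=1,
        ):
            seeds[tuple(masked[pick])] = lab
        out = watershed_flood(_vol(relief), _labels(seeds), _mask(mask))
        expected = oracles.scan_watershed(relief, seeds, mask)
        assert np.array_equal(out.data, expected)


class TestApplyForeground:
    def test_all_true_keeps_labels(self, rng):
        lab = rng.integers(0, 4, size=(4, 4, 4))
        out = apply_foreground(_labels(lab), _mask(np.ones((4, 4, 4))))
        assert np.array_equal(out.data, lab)

    def test_all_false_zeroes_labels(self, rng):
        lab = rng.integers(0, 4, size=(4, 4, 4))
        out = apply_foreground(_labels(lab), _mask(np.zeros((4, 4, 4))))
        assert not out.data.any()

    def test_random_case_equals_pointwise_product(self, rng):
        lab = rng.integers(0, 5, size=(4, 4, 4))
        fg = rng.random((4, 4, 4)) > 0.5
        out = apply_foreground(_labels(lab), _mask(fg))
        assert np.array_equal(out.data, lab * fg)


class TestContactRatio:
    def test_two_adjacent_unit_voxels(self):
        lab = np.zeros((4, 4, 4), int)
        lab[1, 1, 1] = 1
        lab[2, 1, 1] = 2
        assert contact_ratio(_labels(lab), 1, 2) == pytest.approx(1.0 / 6.0)

    def test_no_shared_face_gives_zero(self):
        lab = np.zeros((5, 3, 3), int)
        lab[0, 0, 0] = 1
        lab[4, 2, 2] = 2
        assert contact_ratio(_labels(lab), 1, 2) == 0.0

    def test_symmetry(self, rng):
        lab = rng.integers(0, 3, size=(5, 5, 5))
        lab[0, 0, 0] = 1
        lab[4, 4, 4] = 2
        lv = _labels(lab)
        assert contact_ratio(lv, 1, 2) == contact_ratio(lv, 2, 1)

    def test_missing_label_rejected(self):
        lab = np.zeros((3, 3, 3), int)
        lab[0, 0, 0] = 1
        with pytest.raises(MissingLabelError):
            contact_ratio(_labels(lab), 1, 9)

    @pytest.mark.parametrize("seed", range(8))
    def test_in_unit_interval_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        lab = rng.integers(0, 4, size=(5, 5, 5))
        present = np.unique(lab)
        present = present[present > 0]
        if len(present) < 2:
            pytest.skip("needs two labels")
        lv = _labels(lab)
        i, j = int(present[0]), int(present[1])
        r = contact_ratio(lv, i, j)
        assert 0.0 <= r <= 1.0
        assert r == pytest.approx(oracles.brute_contact_ratio(lab, i, j))


class TestMergeSubunits:
    def test_pair_above_threshold_merges(self):
        lab = np.zeros((4, 4, 4), int)
        lab[:2] = 1
        lab[2:] = 2
        out = merge_subunits(_labels(lab), 0.2)
        assert out.labels().tolist() == [1]

    def test_all_below_threshold_unchanged(self):
        lab = np.zeros((4, 4, 4), int)
        lab[:2] = 1
        lab[2:] = 2
        out = merge_subunits(_labels(lab), 0.5)
        assert np.array_equal(out.data, lab)

    def test_chain_cascade_collapses_to_single_label(self):
        # three slabs: merging the closest pair raises the next ratio over
        # the threshold, cascading to one label
        lab = np.zeros((6, 4, 4), int)
        lab[:2] = 1
        lab[2:4] = 2
        lab[4:] = 3
        out = merge_subunits(_labels(lab), 0.2)
        assert out.labels().size == 1
        expected = oracles.oracle_merge(lab, 0.2)
        assert np.array_equal(out.data, expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recompute_everything_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = rng.integers(0, 6, size=(6, 6, 5))
        thr = float(rng.uniform(0.05, 0.6))
        out = merge_subunits(_labels(lab), thr)
        expected = oracles.oracle_merge(lab, thr)
        assert np.array_equal(out.data > 0, lab > 0)  # foreground untouched
        assert np.array_equal(out.data, expected)

    def test_never_increases_label_count_and_conserves_voxels(self, rng):
        lab = rng.integers(0, 8, size=(7, 7, 6))
        lv = _labels(lab)
        out = merge_subunits(lv, 0.15)
        assert out.labels().size <= lv.labels().size
        assert (out.data > 0).sum() == (lab > 0).sum()


class TestSegmentLobules:
    def test_deterministic_for_fixed_input(self, small_phantom, default_pre, default_seg):
        vol, _ = small_phantom
        a = segment_lobules(vol, default_pre, default_seg)
        b = segment_lobules(vol, default_pre, default_seg)
        assert np.array_equal(a.data, b.data)

    def test_uniform_volume_fails_cleanly(self, default_pre, default_seg):
        vol = _vol(np.full((12, 12, 8), 200.0))
        with pytest.raises((DegenerateHistogramError, EmptySLAError, NoSeedError)):
            segment_lobules(vol, default_pre, default_seg)

    def test_mismatched_region_shape_rejected(self, default_pre, default_seg):
        vol = _vol(np.zeros((8, 8, 8)))
        region = _mask(np.ones((4, 4, 4)))
        with pytest.raises(ConsistencyError):
            segment_lobules(vol, default_pre, default_seg, region=region)


def test_invalid_segmentation_params_rejected():
    with pytest.raises(ParameterError):
        SegmentationParams(distance_threshold=0.0)
    with pytest.raises(ParameterError):
        SegmentationParams(seed_connectivity=10)
    with pytest.raises(ParameterError):
        SegmentationParams(merge_threshold=0.0)
    with pytest.raises(ParameterError):
        SegmentationParams(relief_source="grayscale")
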