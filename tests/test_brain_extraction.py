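import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csvd import brain_extraction as bx
from csvd import phantom
from csvd.errors import ConfigError, DegenerateImageError, EmptyMaskError, ShapeError
from csvd.image_io import GrayscaleSlice

from .conftest import flood_fill_components, partitions_equal


class TestBinarize:
    def test_fixed_threshold(self):
        mask = bx.binarize(np.array([[0, 10], [200, 255]]), 100)
        assert np.array_equal(mask, [[False, False], [True, True]])

    def test_otsu_matches_fixed_on_bimodal(self, rng):
        # exhaustive-sweep oracle: any threshold in the (0, 200) gap yields
        # the same mask, so otsu must agree with fixed(100)
        pixels = np.where(rng.uniform(size=(32, 32)) < 0.4, 0, 200).astype(np.uint8)
        gap_masks = {bx.binarize(pixels, t).tobytes() for t in range(1, 201)}
        assert len(gap_masks) == 1  # sweep confirms a single mask across the gap
        assert np.array_equal(bx.binarize(pixels, "otsu"), bx.binarize(pixels, 100))

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            bx.binarize(np.zeros((8, 8)), "otsu")

    def test_unknown_policy(self):
        with pytest.raises(ConfigError):
            bx.binarize(np.zeros((4, 4)), "median")


class TestInverseBinarize:
    def test_simple(self):
        assert np.array_equal(bx.inverse_binarize(np.array([[0, 255]]), 100), [[True, False]])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 254))
    def test_partition_property(self, seed, threshold):
        pixels = np.random.default_rng(seed).integers(0, 256, size=(12, 12))
        fwd = bx.binarize(pixels, threshold)
        inv = bx.inverse_binarize(pixels, threshold)
        assert np.all(fwd ^ inv)


class TestLabelComponents:
    def test_diagonal_pixels(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert bx.label_components(mask, connectivity=4).count == 2
        assert bx.label_components(mask, connectivity=8).count == 1

    def test_area_sum_invariant(self, rng):
        mask = rng.uniform(size=(20, 20)) < 0.4
        comps = bx.label_components(mask)
        assert comps.areas.sum() == mask.sum()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(25):
            mask = rng.uniform(size=(32, 32)) < rng.uniform(0.2, 0.7)
            comps = bx.label_components(mask, connectivity)
            labels, count = flood_fill_components(mask, connectivity)
            assert partitions_equal(comps.labels, comps.count, labels, count)


class TestRemoveLargest:
    def test_keeps_smaller(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:10, 0:10] = True  # 100 px
        mask[15:16, 0:7] = True  # 7 px
        out = bx.remove_largest(mask)
        assert out.sum() == 7
        assert out[15, 3]

    def test_single_component_leaves_empty(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:3] = True
        assert bx.remove_largest(mask).sum() == 0

    def test_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            bx.remove_largest(np.zeros((4, 4), dtype=bool))

    def test_tie_removes_lowest_id(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0:2] = True  # component 1 (first in scan order)
        mask[4, 0:2] = True  # component 2, same area
        out = bx.remove_largest(mask)
        assert not out[0].any() and out[4].sum() == 2

    def test_strictly_decreases_area(self, rng):
        for _ in range(20):
            mask = rng.uniform(size=(16, 16)) < 0.3
            if bx.label_components(mask).count >= 2:
                assert bx.remove_largest(mask).sum() < mask.sum()


class TestCombineRegions:
    def test_plain_or(self):
        a = np.array([[True, False], [False, False]])
        b = np.array([[False, False], [False, True]])
        assert np.array_equal(bx.combine_regions(a, b), a | b)

    def test_idempotent_union(self, rng):
        a = rng.uniform(size=(10, 10)) < 0.3
        assert np.array_equal(bx.combine_regions(a, a), a)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            bx.combine_regions(np.zeros((2, 2), dtype=bool), np.zeros((3, 3), dtype=bool))

    def test_bbox_restriction_drops_exterior(self):
        # component inside the box is kept, one spilling past it is dropped
        a = np.zeros((12, 12), dtype=bool)
        a[4:6, 4:6] = True  # inside bbox (2,2,10,10)
        b = np.zeros((12, 12), dtype=bool)
        b[0, :] = True  # touches rows outside the box
        out = bx.combine_regions(a, b, cranium_bbox=(2, 2, 10, 10))
        assert out[4:6, 4:6].all() and not out[0].any()

    def test_empty_a_gives_filtered_b(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        b[3:5, 3:5] = True
        out = bx.combine_regions(a, b, cranium_bbox=(1, 1, 7, 7))
        assert np.array_equal(out, b)


class TestMedianFilter:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert bx.median_filter_mask(mask, 3).sum() == 0

    def test_solid_block_unchanged(self):
        # a solid 10x10 block spanning the grid survives (edge replication);
        # note a block with exposed corners would lose them (4/9 ones)
        mask = np.ones((10, 10), dtype=bool)
        assert np.array_equal(bx.median_filter_mask(mask, 3), mask)

    def test_interior_of_embedded_block_survives(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:11, 1:11] = True
        out = bx.median_filter_mask(mask, 3)
        assert out[2:10, 2:10].all()
        assert not out[0].any()

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            bx.median_filter_mask(np.zeros((4, 4), dtype=bool), 4)

    def test_matches_bruteforce_oracle(self, rng):
        # per-pixel neighborhood count with edge replication
        for _ in range(10):
            mask = rng.uniform(size=(16, 16)) < rng.uniform(0.2, 0.8)
            padded = np.pad(mask, 1, mode="edge")
            expected = np.zeros_like(mask)
            for r in range(16):
                for c in range(16):
                    expected[r, c] = padded[r : r + 3, c : c + 3].sum() >= 5
            assert np.array_equal(bx.median_filter_mask(mask, 3), expected)


class TestBrainGeometry:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 7] = True
        region = bx.brain_geometry(mask)
        assert region.bbox == (5, 7, 6, 8)
        assert region.centroid == (5.0, 7.0)
        assert region.area_px == 1
        assert region.area_mm2 is None

    def test_block_with_spacing(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        region = bx.brain_geometry(mask, pixel_spacing_mm=0.5)
        assert region.area_px == 9
        assert region.area_mm2 == pytest.approx(2.25)
        assert region.centroid == (3.0, 3.0)

    def test_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            bx.brain_geometry(np.zeros((4, 4), dtype=bool))

    def test_disk_area_analytic(self, small_spec):
        # analytic oracle: the true brain disk (classes 1-3) has area ~ pi r^2
        _, truth = phantom.generate_slice(small_spec, seed=0)
        region = bx.brain_geometry(np.isin(truth.classes, [1, 2, 3]))
        r = small_spec.brain_radius_frac * small_spec.image_size
        assert region.area_px == pytest.approx(np.pi * r * r, rel=0.05)


class TestExtractBrain:
    def test_phantom_recovers_brain(self, small_pair):
        slc, truth = small_pair
        result = bx.extract_brain(slc)
        brain_true = np.isin(truth.classes, [1, 2, 3])
        retained = (result.region.mask & brain_true).sum() / brain_true.sum()
        assert retained >= 0.99
        assert (result.region.mask & result.intermediates["cranium"]).sum() == 0

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateImageError):
            bx.extract_brain(GrayscaleSlice(np.zeros((32, 32), dtype=np.uint8)))

    def test_mask_excludes_largest_component(self, small_pair):
        slc, _ = small_pair
        result = bx.extract_brain(slc)
        step1 = bx.binarize(slc, result.threshold)
        comps = bx.label_components(step1)
        largest = int(np.argmax(comps.areas)) + 1
        assert not (result.region.mask & (comps.labels == largest)).any()

    def test_masked_slice_zero_outside(self, small_pair):
        slc, _ = small_pair
        result = bx.extract_brain(slc)
        assert np.all(result.masked.pixels[~result.region.mask] == 0)
        assert np.array_equal(
            result.masked.pixels[result.region.mask], slc.pixels[result.region.mask]
        )

    def test_intermediates_present(self, small_pair):
        result = bx.extract_brain(small_pair[0])
        assert set(result.intermediates) == {
            "binarized",
            "cranium",
            "shell_removed",
            "inverse",
            "union",
            "median",
        }
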