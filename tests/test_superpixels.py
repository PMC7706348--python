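import numpy as np
import pytest
from scipy import ndimage

from flowerseg.io_core import PixelCoord, RgbImage
from flowerseg.superpixels import build_ground_truth, merge_regions, slic_segment

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def assert_partition(labels, n_segments):
    found = np.unique(labels)
    assert found.min() == 0 and found.max() == n_segments - 1
    assert len(found) == n_segments  # gap-free
    for lab in found:
        _, k = ndimage.label(labels == lab, structure=FOUR)
        assert k == 1, f"segment {lab} is not 4-connected"


@pytest.fixture
def bipartite():
    two = np.zeros((40, 80, 3), np.uint8)
    two[:, 40:] = 255
    return RgbImage(two, id="two")


class TestSlic:
    def test_partition_and_connectivity_on_random_image(self, rng):
        img = RgbImage(rng.integers(0, 256, (80, 80, 3)).astype(np.uint8))
        spx = slic_segment(img, 25)
        assert_partition(spx.labels, spx.n_segments)
        assert 0.5 * 25 <= spx.n_segments <= 1.5 * 25

    def test_target_count_roughly_honored(self, rng):
        img = RgbImage(rng.integers(0, 256, (100, 100, 3)).astype(np.uint8))
        spx = slic_segment(img, 25)
        assert abs(spx.n_segments - 25) <= 5  # within ±20%

    def test_single_segment(self, rng):
        img = RgbImage(rng.integers(0, 256, (30, 30, 3)).astype(np.uint8))
        spx = slic_segment(img, 1)
        assert spx.n_segments == 1 and (spx.labels == 0).all()

    def test_boundary_adherence_on_bipartite(self, bipartite):
        spx = slic_segment(bipartite, 2)
        assert spx.n_segments == 2
        for lab in range(2):
            vals = np.unique(bipartite.pixels[:, :, 0][spx.labels == lab])
            assert len(vals) == 1  # each segment's color is pure

    def test_too_many_segments_rejected(self, rng):
        img = RgbImage(rng.integers(0, 256, (10, 10, 3)).astype(np.uint8))
        with pytest.raises(ValueError):
            slic_segment(img, 101)


class TestMerge:
    def test_identity_merge_keeps_superpixels(self, rng):
        img = RgbImage(rng.integers(0, 256, (60, 60, 3)).astype(np.uint8))
        spx = slic_segment(img, 12)
        merged = merge_regions(spx, img, spx.n_segments)
        assert merged.n_regions == spx.n_segments
        # identity merge: region partition equals superpixel partition
        assert len(np.unique(merged.region_labels + 1000 * spx.labels)) == spx.n_segments

    def test_bipartite_merges_to_pure_colors(self, bipartite):
        spx = slic_segment(bipartite, 10)
        merged = merge_regions(spx, bipartite, 2)
        assert merged.n_regions == 2
        for lab in range(2):
            vals = np.unique(bipartite.pixels[:, :, 0][merged.region_labels == lab])
            assert len(vals) == 1

    def test_ten_to_one_ratio(self, rng):
        # the production configuration merges 15,000 superpixels into 1,500
        # regions; same 10:1 ratio exercised at desk scale
        img = RgbImage(rng.integers(0, 256, (90, 90, 3)).astype(np.uint8))
        spx = slic_segment(img, 80)
        target = spx.n_segments // 10
        merged = merge_regions(spx, img, target)
        assert merged.n_regions == target
        assert len(merged.centers) == target
        # every merged region is a union of whole superpixels
        for lab in range(target):
            member_spx = np.unique(spx.labels[merged.region_labels == lab])
            for s in member_spx:
                assert (merged.region_labels[spx.labels == s] == lab).all()

    def test_centers_lie_inside_their_region(self, rng):
        img = RgbImage(rng.integers(0, 256, (50, 50, 3)).astype(np.uint8))
        spx = slic_segment(img, 16)
        merged = merge_regions(spx, img, max(2, spx.n_segments // 3))
        for i, c in enumerate(merged.centers):
            assert merged.region_labels[c.row, c.col] == i

    def test_invalid_target_rejected(self, rng):
        img = RgbImage(rng.integers(0, 256, (40, 40, 3)).astype(np.uint8))
        spx = slic_segment(img, 9)
        with pytest.raises(ValueError):
            merge_regions(spx, img, spx.n_segments + 1)


class TestGroundTruth:
    def test_one_mark_lights_whole_segment(self, rng):
        img = RgbImage(rng.integers(0, 256, (40, 40, 3)).astype(np.uint8))
        spx = slic_segment(img, 9)
        mark = PixelCoord(7, 7)
        gt = build_ground_truth(spx, [mark])
        seg = spx.labels[7, 7]
        assert np.array_equal(gt.values, spx.labels == seg)

    def test_two_marks_same_segment_idempotent(self, rng):
        img = RgbImage(rng.integers(0, 256, (40, 40, 3)).astype(np.uint8))
        spx = slic_segment(img, 4)
        seg = spx.labels[10, 10]
        rows, cols = np.nonzero(spx.labels == seg)
        marks = [PixelCoord(int(rows[0]), int(cols[0])), PixelCoord(int(rows[-1]), int(cols[-1]))]
        assert np.array_equal(
            build_ground_truth(spx, marks).values,
            build_ground_truth(spx, marks[:1]).values,
        )

    def test_area_sum_for_distinct_segments(self, rng):
        img = RgbImage(rng.integers(0, 256, (60, 60, 3)).astype(np.uint8))
        spx = slic_segment(img, 9)
        areas = spx.segment_areas()
        segs = np.unique(spx.labels)[:3]
        marks = []
        for s in segs:
            r, c = np.nonzero(spx.labels == s)
            marks.append(PixelCoord(int(r[0]), int(c[0])))
        gt = build_ground_truth(spx, marks)
        assert gt.true_count == sum(areas[s] for s in segs)

    def test_empty_marks_all_false(self, rng):
        img = RgbImage(rng.integers(0, 256, (40, 40, 3)).astype(np.uint8))
        spx = slic_segment(img, 4)
        assert build_ground_truth(spx, []).true_count == 0

    def test_mask_is_union_of_whole_superpixels(self, rng):
        img = RgbImage(rng.integers(0, 256, (50, 50, 3)).astype(np.uint8))
        spx = slic_segment(img, 12)
        gt = build_ground_truth(spx, [PixelCoord(3, 3), PixelCoord(40, 44)])
        for lab in range(spx.n_segments):
            vals = np.unique(gt.values[spx.labels == lab])
            assert len(vals) == 1
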