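"""Cropping, squaring and writing of segment images."""

import numpy as np
import pytest
from PIL import Image

from chemseg import PageImage, BinaryMask, Segment, crop_segment, pad_to_square, segment_page
from chemseg.segmentation import write_segments
from chemseg.errors import EmptyMaskError, InvalidParameterError


@pytest.fixture
def textured_page():
    rng = np.random.default_rng(4)
    return PageImage(rng.integers(0, 255, (40, 50), dtype=np.uint8).astype(np.uint8),
                     dpi=None, source_id="tex")


class TestCropSegment:
    def test_full_page_mask_is_identity(self, textured_page):
        mask = BinaryMask(np.ones(textured_page.shape, dtype=bool))
        seg = crop_segment(textured_page, mask)
        assert np.array_equal(seg.pixels, textured_page.pixels)
        assert seg.bbox == (0, 0, 39, 49)

    def test_single_pixel_mask(self):
        arr = np.full((10, 10), 255, dtype=np.uint8)
        arr[3, 4] = 0
        member = np.zeros((10, 10), dtype=bool)
        member[3, 4] = True
        seg = crop_segment(PageImage(arr, dpi=None), BinaryMask(member))
        assert seg.pixels.shape == (1, 1) and seg.pixels[0, 0] == 0
        assert seg.bbox == (3, 4, 3, 4)

    def test_off_mask_bbox_pixels_stay_white(self, textured_page):
        member = np.zeros(textured_page.shape, dtype=bool)
        member[10:20, 10:12] = True   # L-shape
        member[18:20, 10:25] = True
        seg = crop_segment(textured_page, BinaryMask(member))
        expected = np.full((10, 15), 255, dtype=np.uint8)
        win = member[10:20, 10:25]
        expected[win] = textured_page.pixels[10:20, 10:25][win]
        assert np.array_equal(seg.pixels, expected)
        assert (seg.pixels[0:8, 2:] == 255).all()  # off-mask corner untouched

    def test_ink_conservation(self, textured_page):
        """Multiset of non-white segment pixels equals page values under the mask."""
        rng = np.random.default_rng(8)
        member = rng.random(textured_page.shape) < 0.3
        member[0, 0] = True
        seg = crop_segment(textured_page, BinaryMask(member))
        page_vals = np.sort(textured_page.pixels[member & (textured_page.pixels < 255)])
        seg_vals = np.sort(seg.pixels[seg.pixels < 255])
        assert np.array_equal(page_vals, seg_vals)

    def test_empty_mask_errors(self, textured_page):
        with pytest.raises(EmptyMaskError):
            crop_segment(textured_page, BinaryMask(np.zeros(textured_page.shape, bool)))


class TestPadToSquare:
    def _seg(self, h, w, fill=7):
        return Segment(np.full((h, w), fill, dtype=np.uint8), (0, 0, h - 1, w - 1), "p", "m")

    def test_square_input_unchanged_and_idempotent(self):
        seg = self._seg(50, 50)
        out = pad_to_square(seg, 0)
        assert np.array_equal(out.pixels, seg.pixels)
        again = pad_to_square(out, 0)
        assert np.array_equal(again.pixels, out.pixels)

    def test_even_remainder_splits_symmetrically(self):
        out = pad_to_square(self._seg(20, 30), 0)
        assert out.pixels.shape == (30, 30)
        assert (out.pixels[0:5] == 255).all() and (out.pixels[25:] == 255).all()
        assert (out.pixels[5:25] == 7).all()

    def test_odd_remainder_extra_at_bottom(self):
        out = pad_to_square(self._seg(21, 30), 0)
        assert out.pixels.shape == (30, 30)
        assert (out.pixels[0:4] == 255).all() and (out.pixels[25:] == 255).all()
        assert (out.pixels[4:25] == 7).all()

    def test_padding_preserves_nonwhite_count(self):
        rng = np.random.default_rng(2)
        seg = Segment(rng.integers(0, 255, (13, 29), dtype=np.uint8).astype(np.uint8),
                      (0, 0, 12, 28), "p", "m")
        out = pad_to_square(seg, 0)
        assert (out.pixels < 255).sum() == (seg.pixels < 255).sum()

    def test_rescale_to_target(self):
        out = pad_to_square(self._seg(20, 30), 64)
        assert out.pixels.shape == (64, 64)

    def test_negative_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            pad_to_square(self._seg(5, 5), -1)


class TestSegmentPage:
    def test_empty_mask_list(self, textured_page):
        assert segment_page(textured_page, []) == []

    def test_two_disjoint_masks_two_segments(self):
        arr = np.full((30, 30), 255, dtype=np.uint8)
        arr[2:6, 2:6] = 10
        arr[20:26, 20:27] = 20
        page = PageImage(arr, dpi=None, source_id="two")
        m1 = np.zeros((30, 30), bool); m1[2:6, 2:6] = True
        m2 = np.zeros((30, 30), bool); m2[20:26, 20:27] = True
        segs = segment_page(page, [BinaryMask(m1, "a"), BinaryMask(m2, "b")])
        assert [s.mask_id for s in segs] == ["a", "b"]
        assert (segs[0].pixels < 255).sum() == 16
        assert (segs[1].pixels < 255).sum() == 42

    def test_duplicate_masks_produce_duplicate_segments(self, textured_page):
        member = np.zeros(textured_page.shape, bool)
        member[5:9, 5:9] = True
        segs = segment_page(textured_page, [BinaryMask(member, "x"), BinaryMask(member, "y")])
        assert len(segs) == 2
        assert np.array_equal(segs[0].pixels, segs[1].pixels)

    def test_failing_mask_skipped_with_warning(self, textured_page, caplog):
        good = np.zeros(textured_page.shape, bool); good[1:5, 1:5] = True
        empty = np.zeros(textured_page.shape, bool)
        with caplog.at_level("WARNING"):
            segs = segment_page(textured_page, [BinaryMask(good, "g"), BinaryMask(empty, "e")])
        assert len(segs) == 1 and segs[0].mask_id == "g"
        assert any("skipping" in r.message for r in caplog.records)


def test_write_segments_roundtrip(tmp_path, textured_page):
    member = np.zeros(textured_page.shape, bool)
    member[4:14, 6:16] = True
    seg = pad_to_square(crop_segment(textured_page, BinaryMask(member, "m0")), 0)
    paths = write_segments([seg], tmp_path)
    assert paths[0].name == "tex_m0.png"
    back = np.asarray(Image.open(paths[0]), dtype=np.uint8)
    assert np.array_equal(back, seg.pixels)
    sidecar = tmp_path / "segments.json"
    assert sidecar.exists()
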