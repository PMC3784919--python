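"""Preprocessing: gray conversion, masking, downsampling, histogram
matching, reference selection, volume masks."""

import warnings

import numpy as np
import pytest

from histostack.core import Section2D, SectionSeries, Volume3D
from histostack.preprocess import (
    MorphologyParams,
    background_mask,
    downsample,
    match_histogram,
    rgb_to_gray,
    select_reference,
    threshold_mask,
    transfer_mask,
)
from histostack.transforms import AffineTransform3D


class TestRgbToGray:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((30, 60, 90), 60), ((255, 255, 255), 255), ((10, 20, 40), 23)],
    )
    def test_equal_weight_mean_with_rounding(self, rgb, expected):
        s = Section2D(np.array([[rgb]], dtype=np.uint8))
        assert rgb_to_gray(s).pixels[0, 0] == expected

    def test_wrong_channel_count_rejected(self):
        s = Section2D(np.zeros((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            rgb_to_gray(s)


class TestBackgroundMask:
    def test_disc_with_noise_pixels_cleaned(self, rng):
        img = np.zeros((128, 128))
        rr, cc = np.mgrid[0:128, 0:128]
        disc = (rr - 64) ** 2 + (cc - 64) ** 2 <= 50**2
        img[disc] = 200.0
        noise_idx = rng.integers(0, 128, (20, 2))
        for r, c in noise_idx:
            if not disc[r, c]:
                img[r, c] = 220.0
        mask = background_mask(Section2D(img), MorphologyParams())
        # the retained component is the disc, isolated pixels are gone
        assert (mask & ~disc).sum() < 50
        assert (mask & disc).sum() > 0.9 * disc.sum()

    def test_constant_zero_image_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = background_mask(Section2D(np.zeros((16, 16))))
        assert not mask.any()

    def test_small_components_dropped_by_fraction(self):
        img = np.zeros((64, 64))
        img[10:42, 10:42] = 200.0  # ~1000 px
        img[60:62, 60:63] = 200.0  # ~6 px
        mask = background_mask(
            Section2D(img),
            MorphologyParams(erode_radius=0, dilate_radius=0,
                             min_component_fraction=0.1),
        )
        assert mask[20, 20]
        assert not mask[60:, 60:].any()

    def test_invariant_to_global_gain(self, tissue_sections):
        s = tissue_sections[len(tissue_sections) // 2]
        m1 = background_mask(s)
        m2 = background_mask(s.with_pixels(np.asarray(s.pixels, float) * 3.7))
        assert np.array_equal(m1, m2)


class TestDownsample:
    def test_constant_block_mean(self):
        s = Section2D(np.full((4, 4), 7.0), pixel_size=(42, 42))
        out = downsample(s, 2)
        assert out.shape == (2, 2)
        assert np.allclose(out.pixels, 7.0)

    def test_block_mean_value(self):
        s = Section2D(np.array([[0.0, 2], [4, 6]]))
        assert downsample(s, 2).pixels[0, 0] == pytest.approx(3.0)

    def test_pixel_size_metadata_doubles(self):
        s = Section2D(np.zeros((10, 10)), pixel_size=(42.0, 42.0))
        assert downsample(s, 2).pixel_size == (84.0, 84.0)

    def test_factor_too_large_rejected(self):
        with pytest.raises(ValueError):
            downsample(Section2D(np.zeros((4, 4))), 5)


class TestSelectReference:
    def test_single_section(self, tissue_sections):
        one = SectionSeries([tissue_sections[0]], spacing=200.0)
        assert select_reference(one) == 0

    def test_median_gain_section_selected(self, tissue_sections):
        base = tissue_sections[len(tissue_sections) // 2]
        m = background_mask(base)
        secs = []
        for i, g in enumerate((0.5, 1.0, 2.0)):
            s = Section2D(
                np.asarray(base.pixels, float) * g,
                pixel_size=base.pixel_size,
                index=i,
                mask=m,
            )
            secs.append(s)
        assert select_reference(SectionSeries(secs, spacing=200.0)) == 1

    def test_tie_breaks_to_lower_index(self, tissue_sections):
        base = tissue_sections[len(tissue_sections) // 2]
        dup = Section2D(base.pixels, pixel_size=base.pixel_size, index=0)
        dup2 = Section2D(base.pixels, pixel_size=base.pixel_size, index=1)
        assert select_reference(SectionSeries([dup, dup2], spacing=200.0)) == 0

    def test_override_wins(self, tissue_sections):
        assert select_reference(tissue_sections, override=3) == 3


class TestMatchHistogram:
    def _sec(self, vals):
        a = np.asarray(vals, dtype=float)
        return Section2D(a, mask=np.ones(a.shape, dtype=bool))

    def test_self_match_is_identity_for_integers(self):
        s = self._sec([[0, 1], [2, 3]])
        assert np.array_equal(match_histogram(s, s).pixels, s.pixels)

    def test_constant_to_constant(self):
        out = match_histogram(self._sec([[7, 7]]), self._sec([[42, 42]]))
        assert np.allclose(out.pixels, 42)

    def test_quantile_mapping_oracle(self):
        out = match_histogram(
            self._sec([[0, 1], [2, 3]]), self._sec([[10, 10], [20, 20]])
        )
        assert np.array_equal(out.pixels, [[10, 10], [20, 20]])

    def test_idempotent(self, tissue_sections):
        ref = tissue_sections[2].with_pixels(
            tissue_sections[2].pixels, mask=background_mask(tissue_sections[2])
        )
        src = tissue_sections[5].with_pixels(
            np.asarray(tissue_sections[5].pixels, float) * 1.7,
            mask=background_mask(tissue_sections[5]),
        )
        once = match_histogram(src, ref)
        twice = match_histogram(once, ref)
        assert np.allclose(once.pixels, twice.pixels)

    def test_empty_foreground_rejected(self):
        s = Section2D(np.zeros((4, 4)), mask=np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            match_histogram(s, s)


class TestThresholdMask:
    def test_otsu_separates_bimodal(self):
        data = np.full((8, 8, 8), 10.0)
        data[2:6, 2:6, 2:6] = 200.0
        v = Volume3D(data, voxel_size=(300, 300, 300))
        mask = threshold_mask(v, method="otsu", closing_radius=0)
        assert np.array_equal(mask.data > 0, data == 200.0)

    def test_fixed_threshold(self):
        data = np.full((8, 8, 8), 10.0)
        data[3:5, 3:5, 3:5] = 200.0
        v = Volume3D(data, voxel_size=(300, 300, 300))
        mask = threshold_mask(v, method=50.0, closing_radius=0)
        assert np.array_equal(mask.data > 0, data == 200.0)

    def test_constant_volume_otsu_rejected(self):
        v = Volume3D(np.ones((8, 8, 8)), voxel_size=(300, 300, 300))
        with pytest.raises(ValueError):
            threshold_mask(v, method="otsu")


class TestTransferMask:
    def _mask(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[3:7, 3:7, 3:7] = 1
        return Volume3D(data, voxel_size=(200, 200, 200))

    def test_identity_same_grid_unchanged(self):
        m = self._mask()
        out = transfer_mask(m, AffineTransform3D(), m)
        assert np.array_equal(out.data, m.data)

    def test_one_voxel_translation_shifts_mask(self):
        m = self._mask()
        t = AffineTransform3D(offset=np.array([200.0, 0.0, 0.0]))  # +x in µm
        out = transfer_mask(m, t, m)
        assert np.array_equal(out.data[:, :, :-1], m.data[:, :, 1:])

    def test_fully_outside_warns_and_is_empty(self):
        m = self._mask()
        t = AffineTransform3D(offset=np.array([1e6, 0.0, 0.0]))
        with pytest.warns(UserWarning):
            out = transfer_mask(m, t, m)
        assert not out.data.any()
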