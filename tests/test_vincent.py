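import numpy as np
import pytest
from scipy import ndimage as ndi

from cecseg.io import GrayImage
from cecseg.preprocess import disk_footprint
from cecseg.vincent import (
    VincentParams,
    asf_filter,
    hdome,
    vincent_markers,
    vincent_segment,
)

from oracles import bf_asf, bf_hdome, bf_regional_maxima


@pytest.fixture
def params():
    return VincentParams()


class TestASF:
    def test_constant_unchanged(self, params):
        img = GrayImage(np.full((20, 20), 0.6))
        assert np.allclose(asf_filter(img, params).pixels, 0.6)

    def test_single_pixel_impulse_removed(self, params):
        img = np.full((16, 16), 0.2)
        img[8, 8] = 0.9
        out = asf_filter(GrayImage(img), params).pixels
        assert out[8, 8] < 0.25

    def test_equals_composition_of_primitives(self, params):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        out = asf_filter(GrayImage(img), params).pixels
        expected = img
        for r in range(1, params.asf_max_radius + 1):
            fp = disk_footprint(r)
            expected = ndi.grey_closing(
                ndi.grey_opening(expected, footprint=fp, mode="reflect"),
                footprint=fp, mode="reflect",
            )
        assert np.array_equal(out, np.clip(expected, 0, 1))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        img = rng.random((14, 14))
        params = VincentParams(asf_max_radius=2)
        out = asf_filter(GrayImage(img), params).pixels
        assert np.allclose(out, np.clip(bf_asf(img, 2, disk_footprint), 0, 1))

    def test_radius_one_is_close_open(self):
        rng = np.random.default_rng(2)
        img = rng.random((18, 18))
        fp = disk_footprint(1)
        out = asf_filter(GrayImage(img), VincentParams(asf_max_radius=1)).pixels
        expected = ndi.grey_closing(
            ndi.grey_opening(img, footprint=fp, mode="reflect"), footprint=fp, mode="reflect"
        )
        assert np.array_equal(out, np.clip(expected, 0, 1))


class TestHDome:
    def test_constant_gives_flat_featureless_dome(self, params):
        # a constant image has no peaks: the dome is flat (and no marker
        # can arise from it), though its level is the degenerate h cap
        img = GrayImage(np.full((12, 12), 0.5))
        dome = hdome(img, params).pixels
        assert np.ptp(dome) == 0.0
        assert dome.max() <= params.hdome_h + 1e-12

    def test_isolated_tall_peak_dome_is_exactly_h(self):
        params = VincentParams(hdome_h=0.1)
        img = np.full((15, 15), 0.2)
        img[7, 7] = 0.5  # height 0.3 > h
        dome = hdome(GrayImage(img), params).pixels
        assert np.isclose(dome[7, 7], 0.1, atol=1e-12)
        assert np.allclose(np.delete(dome.ravel(), 7 * 15 + 7), 0.0, atol=1e-12)

    def test_isolated_short_peak_dome_relative_height_is_peak_height(self):
        params = VincentParams(hdome_h=0.1)
        img = np.full((15, 15), 0.2)
        img[7, 7] = 0.25  # height 0.05 <= h
        dome = hdome(GrayImage(img), params).pixels
        background = np.delete(dome.ravel(), 7 * 15 + 7)
        assert np.ptp(background) < 1e-12
        assert np.isclose(dome[7, 7] - background[0], 0.05, atol=1e-12)

    def test_matches_iterative_reconstruction_oracle(self, params):
        rng = np.random.default_rng(3)
        img = np.round(rng.random((12, 12)), 2)
        dome = hdome(GrayImage(img), params).pixels
        expected = bf_hdome(img, params.hdome_h, np.ones((3, 3), bool))
        assert np.allclose(dome, expected, atol=1e-12)

    def test_dome_bounded_by_h_and_anti_extensive(self, params):
        rng = np.random.default_rng(4)
        img = GrayImage(rng.random((20, 20)))
        dome = hdome(img, params).pixels
        assert dome.min() >= 0.0
        assert dome.max() <= params.hdome_h + 1e-12
        assert np.all(img.pixels - dome <= img.pixels + 1e-12)


class TestMarkers:
    def test_two_isolated_peaks_give_two_markers(self):
        params = VincentParams(min_marker_px=1)  # single-pixel peaks allowed
        img = np.full((20, 20), 0.2)
        img[5, 5] = 0.8
        img[14, 14] = 0.8
        cs, lab = vincent_markers(GrayImage(img), params)
        assert lab.max() == 2
        assert len(cs) == 2

    def test_constant_image_has_no_markers(self, params):
        cs, lab = vincent_markers(GrayImage(np.full((10, 10), 0.4)), params)
        assert len(cs) == 0
        assert lab.max() == 0

    def test_regional_maxima_match_brute_force(self):
        from skimage.morphology import local_maxima

        rng = np.random.default_rng(5)
        for _ in range(20):
            img = rng.integers(0, 5, (12, 12)).astype(float) / 5
            got = local_maxima(img, connectivity=2) & (img > 0)
            expected = bf_regional_maxima(img) & (img > 0)
            assert np.array_equal(got, expected)

    def test_mosaic_marker_count_tracks_cell_count(self):
        # clean mosaic on which the classical chain is operable: border
        # bands wider than the ASF structuring element
        from cecseg.synthetic import MosaicSpec, generate_sample

        sample = generate_sample(
            MosaicSpec(seed=21, noise_sigma=0.01, illumination_gradient=0.0,
                       border_width=3, target_density=1500.0)
        )
        params = VincentParams(asf_max_radius=1)
        filtered = asf_filter(sample.image, params)
        cs, _ = vincent_markers(filtered, params)
        n_true = len(sample.truth_centroids)
        assert abs(len(cs) - n_true) / n_true < 0.2


class TestSegment:
    def test_two_bright_blobs_split_frame_at_bisector(self, params):
        img = np.full((30, 60), 0.3)
        img[13:18, 12:17] = 0.8
        img[13:18, 43:48] = 0.8
        res = vincent_segment(GrayImage(img), params)
        assert res.cell_regions.max() == 2
        # the equidistant split for symmetric blobs is the vertical midline
        line_cols = np.nonzero(res.border_mask.mask.any(axis=0))[0]
        assert np.all(np.abs(line_cols - 29.5) <= 2)

    def test_region_count_equals_marker_count_and_partitions_frame(self):
        rng = np.random.default_rng(6)
        img = ndi.gaussian_filter(rng.random((40, 40)), 2)
        img = (img - img.min()) / np.ptp(img)
        gimg = GrayImage(img)
        filtered = asf_filter(gimg, VincentParams())
        _, markers = vincent_markers(filtered, VincentParams())
        res = vincent_segment(gimg, VincentParams())
        assert res.cell_regions.max() == markers.max()
        assert np.all(res.cell_regions > 0)  # full partition

    def test_featureless_image_is_ungradable(self, params):
        res = vincent_segment(GrayImage(np.full((30, 30), 0.5)), params)
        assert not res.gradable
        assert len(res.centroids) == 0
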