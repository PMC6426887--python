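import numpy as np
import pytest
from scipy import ndimage as ndi

from cecseg.labels import BorderLabelMap
from cecseg.postprocess import (
    PostprocessParams,
    binarize,
    extract_centroids,
    remove_small_objects,
)
from cecseg.unet import ProbabilityMap


class TestBinarize:
    @pytest.mark.parametrize("value,expected", [(0.5, 0), (0.7, 1)])
    def test_uniform_maps(self, value, expected):
        pm = ProbabilityMap(np.full((10, 10), value))
        assert np.all(binarize(pm).mask == expected)

    def test_counts_match_threshold(self):
        rng = np.random.default_rng(0)
        probs = rng.random((32, 32))
        k = int((probs >= 0.6).sum())
        assert binarize(ProbabilityMap(probs)).mask.sum() == k

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        pm = ProbabilityMap(rng.random((32, 32)))
        lo = binarize(pm, PostprocessParams(prob_threshold=0.4)).mask
        hi = binarize(pm, PostprocessParams(prob_threshold=0.7)).mask
        assert np.all(hi <= lo)


class TestRemoveSmallObjects:
    def _mask_with_component(self, n_px):
        m = np.zeros((80, 80), dtype=np.uint8)
        m.ravel()[: n_px] = 0
        # build a compact blob of exactly n_px pixels
        filled = 0
        for r in range(80):
            take = min(80, n_px - filled)
            m[r, :take] = 1
            filled += take
            if filled >= n_px:
                break
        return BorderLabelMap(m)

    def test_strict_inequality_boundary(self):
        gone = remove_small_objects(self._mask_with_component(999))
        kept = remove_small_objects(self._mask_with_component(1000))
        assert gone.mask.sum() == 0
        assert kept.mask.sum() == 1000

    def test_mixed_sizes(self):
        m = np.zeros((100, 100), dtype=np.uint8)
        m[:5, :100] = 1  # 500 px
        m[20:35, :100] = 1  # 1500 px
        out = remove_small_objects(BorderLabelMap(m))
        assert out.mask[:5].sum() == 0
        assert out.mask[20:35].sum() == 1500

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = BorderLabelMap((rng.random((64, 64)) > 0.4).astype(np.uint8))
        params = PostprocessParams(min_object_px=50)
        once = remove_small_objects(m, params)
        twice = remove_small_objects(once, params)
        assert np.array_equal(once.mask, twice.mask)


def _square_ring(h, w, top, left, size, thickness=1):
    m = np.zeros((h, w), dtype=np.uint8)
    m[top : top + size, left : left + size] = 1
    t = thickness
    m[top + t : top + size - t, left + t : left + size - t] = 0
    return m


class TestExtractCentroids:
    def test_empty_mask_is_ungradable(self):
        res = extract_centroids(BorderLabelMap(np.zeros((40, 40), dtype=np.uint8)))
        assert not res.gradable
        assert len(res.centroids) == 0

    def test_single_square_cell_centroid_at_center(self):
        m = _square_ring(60, 60, 14, 14, 32)  # encloses a 30x30 interior
        res = extract_centroids(BorderLabelMap(m))
        assert len(res.centroids) == 1
        x, y = res.centroids.points[0]
        assert abs(x - 29.5) <= 1.0 and abs(y - 29.5) <= 1.0

    def test_closed_lattice_yields_one_centroid_per_cell(self):
        # 3x3 closed lattice of 20x20 cells, away from the frame
        m = np.zeros((90, 90), dtype=np.uint8)
        for k in range(4):
            m[10 + 20 * k, 10:71] = 1
            m[10:71, 10 + 20 * k] = 1
        res = extract_centroids(BorderLabelMap(m))
        assert len(res.centroids) == 9
        centers = [(10 + 20 * i + 10, 10 + 20 * j + 10) for i in range(3) for j in range(3)]
        for cx, cy in centers:
            d = np.sqrt(((res.centroids.points - (cx, cy)) ** 2).sum(axis=1)).min()
            assert d <= 3.0

    def test_frame_touching_region_discarded(self):
        # a ring whose enclosed region is fine, plus open background touching frame
        m = _square_ring(50, 50, 10, 10, 20)
        res = extract_centroids(BorderLabelMap(m))
        assert len(res.centroids) == 1
        x, y = res.centroids.points[0]
        assert 10 < x < 30 and 10 < y < 30

    def test_centroids_are_distance_map_local_maxima(self):
        m = np.zeros((90, 90), dtype=np.uint8)
        for k in range(4):
            m[10 + 20 * k, 10:71] = 1
            m[10:71, 10 + 20 * k] = 1
        res = extract_centroids(BorderLabelMap(m))
        dist = ndi.distance_transform_edt(res.border_mask.mask == 0)
        for x, y in res.centroids.points:
            xi, yi = int(x), int(y)
            nb = dist[max(0, yi - 1) : yi + 2, max(0, xi - 1) : xi + 2]
            assert dist[yi, xi] >= nb.max() - 1e-9

    def test_each_centroid_in_its_own_region(self):
        m = np.zeros((90, 90), dtype=np.uint8)
        for k in range(4):
            m[10 + 20 * k, 10:71] = 1
            m[10:71, 10 + 20 * k] = 1
        res = extract_centroids(BorderLabelMap(m))
        seen = set()
        for x, y in res.centroids.points:
            lbl = res.cell_regions[int(y), int(x)]
            assert lbl > 0
            assert lbl not in seen
            seen.add(lbl)
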