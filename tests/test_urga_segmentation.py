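import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctstroke import (EmptyHistogramError, ParameterError, canny_edges,
                      detect_peaks, edge_neighborhood_histogram, region_grow,
                      smooth_histogram, urga)


def peaks_brute_force(h):
    """Exhaustive evaluation of the strict four-step rise/fall condition."""
    h = np.asarray(h, dtype=float)
    out = []
    for i in range(4, h.size - 4):
        rise = sum(np.sign(h[i - j] - h[i - j - 1]) for j in range(4))
        fall = sum(np.sign(h[i + j + 1] - h[i + j]) for j in range(4))
        if rise == 4 and fall == -4:
            out.append(i)
    return out


def grow_bfs_oracle(img, mask, seed_value, tolerance):
    """Breadth-first growth with the frozen-mean admission rule."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, bool)
    seeds = mask & (np.clip(np.round(img), 0, 255) == round(seed_value))
    grown = np.zeros_like(mask)
    stack = list(zip(*np.nonzero(seeds)))
    while stack:
        r, c = stack.pop()
        if grown[r, c]:
            continue
        if abs(img[r, c] - seed_value) > tolerance:
            continue
        grown[r, c] = True
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1] \
                    and mask[rr, cc] and not grown[rr, cc]:
                stack.append((rr, cc))
    return grown


class TestCannyEdges:
    def test_constant_image_has_no_edges(self):
        img = np.full((32, 32), 40.0)
        edges = canny_edges(img, np.ones_like(img, bool), low=1.0, high=2.0)
        assert not edges.any()

    def test_vertical_step_yields_vertical_line(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0
        edges = canny_edges(img, np.ones_like(img, bool), low=5.0, high=20.0)
        cols = np.unique(np.nonzero(edges)[1])
        assert cols.size > 0
        assert np.all(np.abs(cols - 15.5) <= 1.5)

    def test_lesion_boundary_ring_within_two_pixels(self, clean_phantom):
        _, ct, truth = clean_phantom
        from ctstroke import to_display
        from scipy import ndimage
        display = to_display(ct)
        mask = truth.brain_mask
        edges = canny_edges(display, mask, low=2.0, high=8.0)
        boundary = truth.lesion_mask & ~ndimage.binary_erosion(truth.lesion_mask)
        near = ndimage.binary_dilation(boundary, iterations=2)
        # a ring of edge pixels traces the lesion outline
        hits = edges & near
        assert hits.sum() >= 0.5 * boundary.sum()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            canny_edges(np.zeros((8, 8)), np.ones((8, 8), bool),
                        low=3.0, high=2.0)


class TestEdgeNeighborhoodHistogram:
    def test_single_edge_pixel_radius_one(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        edges = np.zeros((4, 4), bool)
        edges[1, 1] = True
        h = edge_neighborhood_histogram(img, edges, radius=1)
        assert h.sum() == 9
        counted = [int(img[r, c]) for r in range(3) for c in range(3)]
        for v in counted:
            assert h[v] == 1

    def test_counts_conserve_dilated_edge_mask_size(self, rng):
        img = rng.uniform(0, 255, size=(20, 20))
        edges = rng.random((20, 20)) < 0.05
        edges[0, 0] = True
        mask = rng.random((20, 20)) < 0.8
        from scipy import ndimage
        near = ndimage.binary_dilation(edges, structure=np.ones((5, 5))) & mask
        h = edge_neighborhood_histogram(img, edges, mask=mask, radius=2)
        assert h.sum() == near.sum()

    def test_matches_nested_loop_count(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(float)
        edges = np.zeros((8, 8), bool)
        edges[2, 3] = edges[6, 1] = True
        h = edge_neighborhood_histogram(img, edges, radius=2)
        expected = np.zeros(256)
        for r in range(8):
            for c in range(8):
                if any(max(abs(r - er), abs(c - ec)) <= 2
                       for er, ec in ((2, 3), (6, 1))):
                    expected[int(img[r, c])] += 1
        np.testing.assert_array_equal(h, expected)

    def test_empty_edge_map_rejected(self):
        with pytest.raises(EmptyHistogramError):
            edge_neighborhood_histogram(np.zeros((4, 4)),
                                        np.zeros((4, 4), bool))


class TestSmoothHistogram:
    def test_impulse_spreads_to_thirds(self):
        h = np.array([0, 0, 9, 0, 0], dtype=float)
        np.testing.assert_allclose(smooth_histogram(h, 3), [0, 3, 3, 3, 0])

    def test_constant_histogram_unchanged(self):
        h = np.full(32, 7.0)
        np.testing.assert_allclose(smooth_histogram(h, 5), h)

    def test_spike_attenuated_below_broad_maximum(self):
        h = np.zeros(64)
        h[10] = 30          # isolated single-bin spike (noise)
        h[30:37] = 25       # broad maximum
        s = smooth_histogram(h, 3)
        assert s[10] < s[33]

    def test_even_width_rejected(self):
        with pytest.raises(ParameterError):
            smooth_histogram(np.ones(16), 4)


class TestDetectPeaks:
    def test_monotone_histogram_has_no_peaks(self):
        assert detect_peaks(np.arange(32, dtype=float)) == []

    def test_tent_peak_detected_at_apex(self):
        h = np.zeros(32)
        p = 12
        for j in range(5):
            h[p - j] = h[p + j] = 10 - 2 * j
        assert detect_peaks(h) == [p]

    def test_plateau_top_produces_no_seed(self):
        h = np.zeros(32)
        h[8:12] = [4, 8, 12, 16]
        h[12] = 16          # two equal maximum bins
        h[13:17] = [12, 8, 4, 2]
        assert detect_peaks(h) == []

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(200):
            h = rng.integers(0, 50, size=256).astype(float)
            assert detect_peaks(h) == peaks_brute_force(h)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=9, max_size=64))
    def test_matches_brute_force_property(self, counts):
        h = np.array(counts, dtype=float)
        assert detect_peaks(h) == peaks_brute_force(h)

    def test_short_histogram_rejected(self):
        with pytest.raises(ParameterError):
            detect_peaks(np.ones(8))


class TestRegionGrow:
    def test_uniform_disk_grows_entirely(self):
        from skimage.morphology import disk
        mask = disk(8).astype(bool)
        img = np.where(mask, 100.0, 0.0)
        grown = region_grow(img, mask, 100.0, tolerance=4.0)
        np.testing.assert_array_equal(grown, mask)

    def test_growth_never_crosses_contrast_boundary(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 20.0   # two patches differing by > 2 * tolerance
        mask = np.ones((10, 10), bool)
        grown = region_grow(img, mask, 0.0, tolerance=4.0)
        assert not grown[:, 5:].any()
        assert grown[:, :5].all()

    def test_matches_bfs_oracle_on_toy_grid(self, rng):
        for _ in range(20):
            img = rng.integers(0, 20, size=(6, 6)).astype(float)
            mask = rng.random((6, 6)) < 0.9
            seed = float(rng.integers(0, 20))
            got = region_grow(img, mask, seed, tolerance=3.0)
            want = grow_bfs_oracle(img, mask, seed, 3.0)
            np.testing.assert_array_equal(got, want)

    def test_absent_seed_value_returns_empty(self):
        img = np.full((5, 5), 10.0)
        grown = region_grow(img, np.ones((5, 5), bool), 200.0, tolerance=4.0)
        assert not grown.any()

    def test_excluded_pixels_stay_unlabeled(self):
        img = np.full((6, 6), 50.0)
        exclude = np.zeros((6, 6), bool)
        exclude[:3] = True
        grown = region_grow(img, np.ones((6, 6), bool), 50.0,
                            tolerance=4.0, exclude=exclude)
        assert not grown[:3].any() and grown[3:].all()


class TestUrga:
    def _two_tissue_image(self):
        rng = np.random.default_rng(5)
        img = np.full((64, 64), 100.0)
        img[:, 32:] = 160.0
        lesion = np.zeros((64, 64), bool)
        rr, cc = np.mgrid[0:64, 0:64]
        lesion[(rr - 20) ** 2 + (cc - 16) ** 2 <= 36] = True
        img[lesion] = 130.0
        img += rng.normal(0, 2.0, img.shape)
        mask = np.ones((64, 64), bool)
        return img, mask, lesion

    def test_lesion_resolves_to_one_region(self):
        img, mask, lesion = self._two_tissue_image()
        labels = urga(img, mask, canny_low=2.0, canny_high=8.0,
                      min_seed_intensity=0.0)
        ids, counts = np.unique(labels[lesion], return_counts=True)
        dominant = ids[np.argmax(counts)]
        pred = labels == dominant
        jacc = (pred & lesion).sum() / (pred | lesion).sum()
        assert jacc >= 0.7

    def test_every_masked_pixel_labeled_exactly_once(self, noisy_phantom):
        _, ct, truth = noisy_phantom
        from ctstroke import anisotropic_smooth, enhance, to_display
        enhanced, _ = enhance(to_display(ct))
        labels = urga(anisotropic_smooth(enhanced), truth.brain_mask)
        assert (labels[truth.brain_mask] > 0).all()
        assert (labels[~truth.brain_mask] == 0).all()

    def test_deterministic(self):
        img, mask, _ = self._two_tissue_image()
        a = urga(img, mask, canny_low=2.0, canny_high=8.0, min_seed_intensity=0.0)
        b = urga(img, mask, canny_low=2.0, canny_high=8.0, min_seed_intensity=0.0)
        np.testing.assert_array_equal(a, b)

    def test_peakless_input_falls_back_to_single_region(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        mask = np.ones((16, 16), bool)
        with pytest.warns(UserWarning):
            labels = urga(img, mask, canny_low=5.0, canny_high=20.0,
                          min_seed_intensity=250.0)  # ceiling kills all seeds
        assert set(np.unique(labels)) == {1}

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            urga(np.zeros((8, 8)), np.zeros((8, 8), bool))
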