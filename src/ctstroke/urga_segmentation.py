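"""Unsupervised region growing (URGA): edge-seeded histogram-peak segmentation.

Classic region growing needs hand-picked seeds.  Here seeds come from the
image itself: a Canny edge map marks tissue boundaries, an intensity
histogram is accumulated over the pixels *near* those edges (where every
tissue class is sampled), the histogram is mean-filtered, and its strict
local peaks — four rising steps in, four falling steps out — become seed
intensities.  Each seed grows a set of 4-connected regions admitting
neighbours whose intensity stays within a tolerance of the seed value.
Peaks below a cerebrospinal-fluid intensity ceiling are never seeded, since
CSF is not stroke-bearing tissue.  The peak/grow cycle repeats on the
still-unlabeled pixels until no peaks remain; leftovers are swept into the
labeled region with the nearest mean intensity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _sk_canny
from skimage.filters import sobel, threshold_otsu

from .errors import EmptyHistogramError, ParameterError

N_BINS = 256

#: display value of ~15 HU under the default brain window; bins below this
#: are treated as CSF and never seeded
DEFAULT_CSF_CEILING = 63.75

DEFAULT_GROW_TOLERANCE = 4.0
DEFAULT_HIST_RADIUS = 2
DEFAULT_SMOOTH_WIDTH = 3

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def default_canny_thresholds(img: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Hysteresis thresholds: high = Otsu of the gradient magnitude inside the
    mask, low = 0.4 * high."""
    grad = sobel(np.asarray(img, dtype=np.float64))
    vals = grad[np.asarray(mask, bool)]
    if vals.size == 0 or np.unique(vals).size < 2:
        return 0.0, 1.0
    high = float(threshold_otsu(vals, nbins=256))
    return 0.4 * high, high


def canny_edges(img: np.ndarray, mask: np.ndarray,
                low: float | None = None, high: float | None = None,
                sigma: float = 1.0) -> np.ndarray:
    """Canny edge map restricted to the mask.

    ``low``/``high`` default to the gradient-Otsu rule of
    :func:`default_canny_thresholds`.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, bool)
    if low is None or high is None:
        d_low, d_high = default_canny_thresholds(img, mask)
        low = d_low if low is None else low
        high = d_high if high is None else high
    if not (0 <= low < high):
        raise ParameterError("Canny thresholds require 0 <= low < high")
    return _sk_canny(img, sigma=sigma, low_threshold=low, high_threshold=high,
                     mask=mask)


def edge_neighborhood_histogram(img: np.ndarray, edges: np.ndarray,
                                mask: np.ndarray | None = None,
                                radius: int = DEFAULT_HIST_RADIUS) -> np.ndarray:
    """Integer histogram of intensities within Chebyshev ``radius`` of an edge.

    Each qualifying pixel is counted once regardless of how many edge pixels
    it neighbours.  Intensities are binned by rounding to [0, 255].
    """
    if radius < 1:
        raise ParameterError("neighborhood radius must be >= 1")
    edges = np.asarray(edges, bool)
    if not edges.any():
        raise EmptyHistogramError("edge map is empty")
    img = np.asarray(img, dtype=np.float64)
    size = 2 * radius + 1
    near = ndimage.binary_dilation(edges, structure=np.ones((size, size), bool))
    if mask is not None:
        near &= np.asarray(mask, bool)
    vals = np.clip(np.round(img[near]), 0, N_BINS - 1).astype(np.intp)
    return np.bincount(vals, minlength=N_BINS)


def smooth_histogram(counts: np.ndarray, width: int = DEFAULT_SMOOTH_WIDTH) -> np.ndarray:
    """Moving-average denoising with shrinking windows at the ends.

    Returns real-valued counts (no re-rounding) so that flat plateaus are not
    manufactured by quantisation.
    """
    if width < 3 or width % 2 == 0:
        raise ParameterError("smoothing width must be an odd integer >= 3")
    counts = np.asarray(counts, dtype=np.float64)
    kernel = np.ones(width)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts), kernel, mode="same")
    return num / den


def detect_peaks(counts: np.ndarray) -> list[int]:
    """Strict histogram peaks: 4 rising steps into bin i, 4 falling steps out.

    A bin i in [4, L-5] is a peak iff sign(H[i-j] - H[i-j-1]) = +1 and
    sign(H[i+j+1] - H[i+j]) = -1 for every j in 0..3; any flat step (a zero
    difference) disqualifies the bin.
    """
    counts = np.asarray(counts, dtype=np.float64)
    L = counts.size
    if L < 9:
        raise ParameterError("histogram must have at least 9 bins")
    d = np.diff(counts)  # d[t] = H[t+1] - H[t]
    rising = d > 0
    falling = d < 0
    peaks = []
    for i in range(4, L - 4):
        if rising[i - 4:i].all() and falling[i:i + 4].all():
            peaks.append(i)
    return peaks


def region_grow(img: np.ndarray, mask: np.ndarray, seed_value: float,
                tolerance: float = DEFAULT_GROW_TOLERANCE,
                exclude: np.ndarray | None = None,
                running_mean: bool = False) -> np.ndarray:
    """Grow 4-connected regions from every masked pixel in the seed bin.

    Admission (default, frozen-mean): a pixel joins iff
    |I(p) - seed_value| <= tolerance — order-invariant, so the result is the
    union of connected components of the admissible set that contain a seed
    pixel.  ``running_mean=True`` instead updates the region mean as pixels
    join (breadth-first, deterministic scan order); this follows the
    admission test against the evolving mean but is order-dependent.

    Returns a boolean array; empty if the seed bin does not occur.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    img = np.asarray(img, dtype=np.float64)
    avail = np.asarray(mask, bool).copy()
    if exclude is not None:
        avail &= ~np.asarray(exclude, bool)
    binned = np.clip(np.round(img), 0, N_BINS - 1)
    seeds = avail & (binned == round(seed_value))
    if not seeds.any():
        return np.zeros_like(avail)

    if not running_mean:
        admissible = avail & (np.abs(img - seed_value) <= tolerance)
        labels, n = ndimage.label(admissible, structure=_FOUR_CONN)
        keep = np.unique(labels[seeds])
        keep = keep[keep > 0]
        return np.isin(labels, keep)

    # running-mean variant: breadth-first growth in raster order
    from collections import deque

    grown = np.zeros_like(avail)
    visited = np.zeros_like(avail)
    rows, cols = img.shape
    total = 0.0
    count = 0
    queue = deque(zip(*np.nonzero(seeds)))
    for r, c in queue:
        visited[r, c] = True
    while queue:
        r, c = queue.popleft()
        mean = total / count if count else seed_value
        if abs(img[r, c] - mean) > tolerance and not seeds[r, c]:
            continue
        grown[r, c] = True
        total += img[r, c]
        count += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and avail[rr, cc] \
                    and not visited[rr, cc]:
                visited[rr, cc] = True
                queue.append((rr, cc))
    return grown


def urga(img: np.ndarray, mask: np.ndarray,
         canny_low: float | None = None, canny_high: float | None = None,
         canny_sigma: float = 1.0,
         hist_radius: int = DEFAULT_HIST_RADIUS,
         smooth_width: int = DEFAULT_SMOOTH_WIDTH,
         tolerance: float = DEFAULT_GROW_TOLERANCE,
         min_seed_intensity: float = DEFAULT_CSF_CEILING,
         running_mean: bool = False,
         max_rounds: int = 10) -> np.ndarray:
    """Full unsupervised segmentation of the masked brain area.

    Returns an integer label map: 0 outside the mask, 1..R inside.  Every
    masked pixel receives exactly one label; the map is deterministic for a
    given input.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ParameterError("brain mask is empty")

    labels = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    edges = canny_edges(img, mask, low=canny_low, high=canny_high,
                        sigma=canny_sigma)

    for _ in range(max_rounds):
        unlabeled = mask & (labels == 0)
        if not unlabeled.any():
            break
        try:
            hist = edge_neighborhood_histogram(img, edges, mask=unlabeled,
                                               radius=hist_radius)
        except EmptyHistogramError:
            break
        smoothed = smooth_histogram(hist, smooth_width)
        peaks = [p for p in detect_peaks(smoothed) if p >= min_seed_intensity]
        if not peaks:
            break
        # most prominent peak first; ties to the darker bin for determinism
        peaks.sort(key=lambda p: (-smoothed[p], p))
        grew_any = False
        for p in peaks:
            region = region_grow(img, mask, float(p), tolerance=tolerance,
                                 exclude=labels > 0, running_mean=running_mean)
            if region.any():
                labels[region] = next_label
                next_label += 1
                grew_any = True
        if not grew_any:
            break

    if next_label == 1:
        warnings.warn("URGA found no histogram peaks; returning the whole mask "
                      "as a single region", stacklevel=2)
        labels[mask] = 1
        return labels

    # final sweep: attach leftovers to the region with the nearest mean intensity
    unlabeled = mask & (labels == 0)
    if unlabeled.any():
        ids = np.arange(1, next_label)
        means = ndimage.mean(img, labels=labels, index=ids)
        vals = img[unlabeled]
        # ties break toward the lower label id via argmin on first occurrence
        nearest = ids[np.argmin(np.abs(vals[:, None] - means[None, :]), axis=1)]
        labels[unlabeled] = nearest
    return labels
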