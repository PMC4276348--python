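"""Advanced correction and red marking of the suspected stroke area.

Candidate pixels must satisfy three conditions simultaneously: they lie on
the suspected hemisphere, their calibrated attenuation falls in the
ischemic-stroke window (30-36 HU inclusive), and they belong to the darkest
fraction (default 30%) of brain-tissue HU values — infarcts are hypodense
relative to the tissue around them.  Marked components smaller than a
minimum area are discarded as noise; everything not marked keeps its
original gray value in the rendered overlay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError
from .io_formats import CTSlice
from .partitioning import REGION_KEYS

DEFAULT_HU_LO = 30.0
DEFAULT_HU_HI = 36.0
DEFAULT_DARK_FRACTION = 0.3

#: minimum marked-component area in pixels (~20 mm^2 at 0.2 mm/px): below the
#: smallest lesions of interest even after noise erodes their HU-window edges,
#: far above any noise speckle
DEFAULT_MIN_COMPONENT_PX = 500

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def darkest_fraction_cut(values, fraction: float = DEFAULT_DARK_FRACTION) -> float:
    """Lower empirical ``fraction``-quantile of the HU values.

    Defined as the value at index ceil(fraction * n) - 1 of the sorted list;
    pixels at or below it form the provisional stroke-value set.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise InputError("cannot take a quantile of an empty value set")
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must lie strictly between 0 and 1")
    idx = math.ceil(fraction * values.size) - 1
    return float(np.sort(values)[max(idx, 0)])


@dataclass
class StrokeMask:
    """Boolean mask of red-marked pixels plus the HU cut actually used."""

    mask: np.ndarray
    hu_cut: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_mm2(self, spacing_mm: float) -> float:
        return self.area_px * spacing_mm ** 2


def build_stroke_mask(ct: CTSlice, parts: dict, side: str,
                      hu_lo: float = DEFAULT_HU_LO, hu_hi: float = DEFAULT_HU_HI,
                      fraction: float = DEFAULT_DARK_FRACTION,
                      min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
                      fraction_scope: str = "brain") -> StrokeMask:
    """Stroke candidate mask on the suspected hemisphere.

    ``fraction_scope`` selects whether the darkest-fraction cut is taken
    over the whole brain mask (default) or only the suspected side.
    An empty mask is a legitimate outcome (no highlight).
    """
    if side not in ("left", "right"):
        raise InputError(f"side must be 'left' or 'right', got {side!r}")
    if fraction_scope not in ("brain", "side"):
        raise ParameterError("fraction_scope must be 'brain' or 'side'")
    side_mask = np.zeros(ct.pixels.shape, dtype=bool)
    brain_mask = np.zeros_like(side_mask)
    for key in REGION_KEYS:
        brain_mask |= parts[key]
        if key[0] == side:
            side_mask |= parts[key]
    scope = side_mask if fraction_scope == "side" else brain_mask
    if not scope.any():
        raise InputError("partition covers no pixels")
    cut = darkest_fraction_cut(ct.pixels[scope], fraction)

    hu = ct.pixels
    mask = side_mask & (hu >= hu_lo) & (hu <= hu_hi) & (hu <= cut)
    if min_component_px > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=_FOUR_CONN)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_component_px) + 1
        if small.size:
            mask &= ~np.isin(labels, small)
    return StrokeMask(mask=mask, hu_cut=cut)


def render_overlay(img: np.ndarray, stroke: StrokeMask | np.ndarray) -> np.ndarray:
    """Replicate the grayscale image to RGB and paint marked pixels pure red."""
    img = np.asarray(img, dtype=np.float64)
    mask = stroke.mask if isinstance(stroke, StrokeMask) else np.asarray(stroke, bool)
    if img.shape != mask.shape:
        raise InputError("image and stroke mask shapes differ")
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    rgb[mask] = (255.0, 0.0, 0.0)
    return rgb
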