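"""Eight-region anatomical partition of the extracted brain.

The brain mask's tight bounding rectangle (by row/column projection) fixes
the brain center; the center row and column split the mask into quadrants,
and a concentric ellipse whose semi-axes are 2/3 of the rectangle's
half-dimensions separates an inner (deep / white-matter) zone from an outer
(peripheral / gray-matter) zone.  Quadrant x zone yields eight regions that
partition the mask exactly.

Region key order (for label exports): left-upper-outer = 1,
left-upper-inner = 2, left-lower-outer = 3, left-lower-inner = 4, then the
same four on the right, ending at right-lower-inner = 8.  "Left"/"right"
are image-coordinate sides; radiological-vs-neurological flips are the
caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

SIDES = ("left", "right")
HALVES = ("upper", "lower")
ZONES = ("outer", "inner")

#: fixed ordering of the eight region keys
REGION_KEYS = tuple((side, half, zone)
                    for side in SIDES for half in HALVES for zone in ZONES)

INNER_AXIS_RATIO = 2.0 / 3.0


@dataclass(frozen=True)
class BoundingRect:
    """Tight axis-aligned bounding rectangle of a mask, with its midpoint."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise InputError("degenerate bounding rectangle")

    @property
    def center_row(self) -> float:
        return (self.row_min + self.row_max) / 2.0

    @property
    def center_col(self) -> float:
        return (self.col_min + self.col_max) / 2.0

    @property
    def half_height(self) -> float:
        return (self.row_max - self.row_min) / 2.0

    @property
    def half_width(self) -> float:
        return (self.col_max - self.col_min) / 2.0


def bounding_rectangle(mask: np.ndarray) -> BoundingRect:
    """Tight bounding rectangle of the true pixels, by projection."""
    mask = np.asarray(mask, bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise InputError("mask is empty")
    return BoundingRect(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))


def partition_eight(mask: np.ndarray, rect: BoundingRect | None = None,
                    axis_ratio: float = INNER_AXIS_RATIO,
                    scale_minor_only: bool = False) -> dict:
    """Split the mask into the eight named regions.

    Half-open quadrant rule: a pixel is on the right iff col >= center_col
    and in the lower half iff row >= center_row.  Ellipse membership counts
    the boundary as inner.  ``scale_minor_only`` scales only the shorter
    rectangle axis by ``axis_ratio`` (the longer one keeps the full half-
    dimension), for the alternative reading of the inner-ellipse geometry.

    Returns a dict mapping each (side, half, zone) key to a boolean mask;
    the eight masks are pairwise disjoint and union exactly to ``mask``.
    """
    mask = np.asarray(mask, bool)
    if rect is None:
        rect = bounding_rectangle(mask)
    if rect.half_height == 0 or rect.half_width == 0:
        raise InputError("bounding rectangle has a zero span; cannot partition")

    rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    lower = rr >= rect.center_row
    right = cc >= rect.center_col

    a_s = axis_ratio * rect.half_width
    b_s = axis_ratio * rect.half_height
    if scale_minor_only:
        if rect.half_width <= rect.half_height:
            b_s = rect.half_height
        else:
            a_s = rect.half_width
    inner = (((cc - rect.center_col) / a_s) ** 2
             + ((rr - rect.center_row) / b_s) ** 2) <= 1.0

    half_sel = {"upper": ~lower, "lower": lower}
    side_sel = {"left": ~right, "right": right}
    zone_sel = {"inner": inner, "outer": ~inner}
    return {
        (side, half, zone): mask & side_sel[side] & half_sel[half] & zone_sel[zone]
        for (side, half, zone) in REGION_KEYS
    }


def partition_label_map(parts: dict) -> np.ndarray:
    """Single integer label image (1..8 in REGION_KEYS order, 0 elsewhere)."""
    first = next(iter(parts.values()))
    out = np.zeros(first.shape, dtype=np.uint8)
    for idx, key in enumerate(REGION_KEYS, start=1):
        out[parts[key]] = idx
    return out
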