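"""Coinciding-regional-location lateralization.

An ischemic infarct is hypodense, so the stroke-bearing hemisphere shows
lower mean brightness in the regions it occupies.  For each of the four
position pairs (upper/lower x inner/outer) the darker side is selected; the
4-0 / 3-1 / 2-2 split of those selections defines three cases that are
resolved into a single suspected hemisphere:

* case 1 (4-0): the common side wins outright.
* case 2 (3-1): if the lone minority region differs from its mirror by less
  than the just-noticeable-difference delta (default 4 display units) it is
  merged into the majority; at or above delta it is flagged dissimilar in
  the trace — either way the majority side is reported.
* case 3 (2-2): when the selections group into two same-side duos (by half
  or by zone), the duo with the smaller mean cross-side difference is merged
  into the other duo's side.  For a diagonal split, the left-vs-right mean
  brightness difference is computed within the upper and within the lower
  half, and the darker side of the half with the larger difference wins.

Exactly one side is always returned (bilateral stroke is rare and outside
this model); every comparison and merge is recorded in an ordered trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .partitioning import HALVES, REGION_KEYS, SIDES, ZONES

DEFAULT_DELTA = 4.0

#: the four position pairs compared across the midline
POSITIONS = tuple((half, zone) for half in HALVES for zone in ZONES)


def region_means(img: np.ndarray, parts: dict) -> dict:
    """Mean display intensity per region; empty regions map to ``None``.

    Emits a warning for empty regions so degenerate masks are visible.
    """
    img = np.asarray(img, dtype=np.float64)
    out = {}
    for key in REGION_KEYS:
        sel = parts[key]
        if sel.any():
            out[key] = float(img[sel].mean())
        else:
            warnings.warn(f"region {key} is empty; excluded from lateralization",
                          stacklevel=2)
            out[key] = None
    return out


def darkest_four(stats: dict) -> list:
    """The darker side's region key for each of the four position pairs.

    Ties (and pairs with one empty region) resolve to the left side; a pair
    with an empty region resolves to its non-empty side.
    """
    selected = []
    for half, zone in POSITIONS:
        left = stats[("left", half, zone)]
        right = stats[("right", half, zone)]
        if left is None and right is None:
            raise InputError(f"both regions of position ({half}, {zone}) are empty")
        if right is None or (left is not None and left <= right):
            selected.append(("left", half, zone))
        else:
            selected.append(("right", half, zone))
    return selected


def _pair_diff(stats: dict, half: str, zone: str) -> float:
    left = stats[("left", half, zone)]
    right = stats[("right", half, zone)]
    if left is None or right is None:
        return 0.0
    return abs(left - right)


def _half_diff(stats: dict, half: str) -> tuple[float, str]:
    """Left-vs-right mean brightness difference within one half; returns
    (|difference|, darker side)."""
    left_vals = [stats[("left", half, z)] for z in ZONES]
    right_vals = [stats[("right", half, z)] for z in ZONES]
    left_vals = [v for v in left_vals if v is not None]
    right_vals = [v for v in right_vals if v is not None]
    lm = float(np.mean(left_vals)) if left_vals else np.inf
    rm = float(np.mean(right_vals)) if right_vals else np.inf
    side = "left" if lm <= rm else "right"
    return abs(lm - rm), side


@dataclass
class LateralizationResult:
    """Suspected hemisphere with the full decision trace."""

    side: str
    case_id: int
    selected_regions: list
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "case_id": self.case_id,
            "selected_regions": [list(k) for k in self.selected_regions],
            "trace": list(self.trace),
        }


def coincide(stats: dict, delta: float = DEFAULT_DELTA) -> LateralizationResult:
    """Resolve the darkest-four selections into one suspected hemisphere."""
    for key in REGION_KEYS:
        if key not in stats:
            raise InputError(f"missing region statistic for {key}")
    selected = darkest_four(stats)
    sides = [key[0] for key in selected]
    n_left = sides.count("left")
    trace = [f"darkest-four selections: "
             + ", ".join("-".join(k) for k in selected)]

    if n_left in (0, 4):
        side = "left" if n_left == 4 else "right"
        trace.append(f"case 1: all four selections on the {side} side")
        return LateralizationResult(side, 1, selected, trace)

    if n_left in (1, 3):
        majority = "left" if n_left == 3 else "right"
        minority_key = next(k for k in selected if k[0] != majority)
        _, half, zone = minority_key
        diff = _pair_diff(stats, half, zone)
        if diff < delta:
            trace.append(
                f"case 2: minority {'-'.join(minority_key)} cross-side "
                f"difference {diff:.3f} < {delta}; merged into the {majority} side")
        else:
            trace.append(
                f"case 2: minority {'-'.join(minority_key)} cross-side "
                f"difference {diff:.3f} >= {delta}; flagged dissimilar; "
                f"{majority} side retained")
        return LateralizationResult(majority, 2, selected, trace)

    # case 3: 2-2 split
    left_pos = {(h, z) for (s, h, z) in selected if s == "left"}
    by_half = {h for (h, _) in left_pos}
    by_zone = {z for (_, z) in left_pos}
    if len(by_half) == 1 or len(by_zone) == 1:
        # the two left selections share a half (or a zone): two aligned duos
        if len(by_half) == 1:
            groups = {h: [(h, z) for z in ZONES] for h in HALVES}
            axis = "half"
        else:
            groups = {z: [(h, z) for h in HALVES] for z in ZONES}
            axis = "zone"
        duo_info = []
        for name, positions in groups.items():
            d = float(np.mean([_pair_diff(stats, h, z) for (h, z) in positions]))
            duo_side = next(s for (s, h, z) in selected
                            if (h, z) in positions)
            duo_info.append((d, name, duo_side))
        duo_info.sort(key=lambda t: (-t[0], t[2] != "left"))
        winner_diff, winner_name, winner_side = duo_info[0]
        loser_diff, loser_name, _ = duo_info[1]
        trace.append(
            f"case 3 (aligned by {axis}): duo '{winner_name}' difference "
            f"{winner_diff:.3f} >= duo '{loser_name}' difference {loser_diff:.3f}; "
            f"merged toward the {winner_side} side")
        return LateralizationResult(winner_side, 3, selected, trace)

    # diagonal split: decide within the upper and lower halves
    du, su = _half_diff(stats, "upper")
    dl, sl = _half_diff(stats, "lower")
    if du > dl or (du == dl and su == "left"):
        side, dwin, name = su, du, "upper"
        dlose = dl
    else:
        side, dwin, name = sl, dl, "lower"
        dlose = du
    trace.append(
        f"case 3 (diagonal split): {name}-half left-right difference "
        f"{dwin:.3f} vs other half {dlose:.3f}; darker side of the {name} "
        f"half is {side}; merged toward {side}")
    return LateralizationResult(side, 3, selected, trace)
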