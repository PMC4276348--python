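import numpy as np
import pytest

from ctstroke import (InputError, coincide, darkest_four, partition_eight,
                      region_means)
from ctstroke.lateralization import POSITIONS
from ctstroke.partitioning import REGION_KEYS


def stats_from(values):
    """Build a stats dict from {(side, half, zone): mean} with defaults 100."""
    stats = {key: 100.0 for key in REGION_KEYS}
    stats.update(values)
    return stats


def mirror_stats(stats):
    flip = {"left": "right", "right": "left"}
    return {(flip[s], h, z): v for (s, h, z), v in stats.items()}


class TestRegionMeans:
    def test_uniform_image_all_means_equal(self):
        mask = np.ones((20, 20), bool)
        parts = partition_eight(mask)
        means = region_means(np.full((20, 20), 42.0), parts)
        assert all(v == pytest.approx(42.0) for v in means.values())

    def test_matches_per_pixel_summation(self, rng):
        mask = np.ones((16, 16), bool)
        img = rng.uniform(0, 255, size=(16, 16))
        parts = partition_eight(mask)
        means = region_means(img, parts)
        for key in REGION_KEYS:
            sel = parts[key]
            total = sum(img[r, c] for r, c in zip(*np.nonzero(sel)))
            assert means[key] == pytest.approx(total / sel.sum())

    def test_empty_region_flagged_none_with_warning(self):
        from ctstroke import BoundingRect
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True  # mask confined to the left-upper quadrant
        parts = partition_eight(mask, rect=BoundingRect(0, 19, 0, 19))
        with pytest.warns(UserWarning):
            means = region_means(np.ones((20, 20)), parts)
        assert any(v is None for v in means.values())


class TestDarkestFour:
    def test_uniformly_darker_left_selects_all_left(self):
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        assert all(k[0] == "left" for k in darkest_four(stats))

    def test_single_darker_right_pair_gives_three_one_split(self):
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        stats[("right", "upper", "inner")] = 80.0
        stats[("left", "upper", "inner")] = 95.0
        sides = [k[0] for k in darkest_four(stats)]
        assert sides.count("left") == 3 and sides.count("right") == 1

    def test_symmetric_stats_tie_break_to_left(self):
        stats = stats_from({})
        assert all(k[0] == "left" for k in darkest_four(stats))

    def test_empty_pair_resolves_to_nonempty_side(self):
        stats = stats_from({("left", "upper", "outer"): None})
        selected = darkest_four(stats)
        assert ("right", "upper", "outer") in selected


class TestCoincide:
    def test_case1_unanimous_side(self):
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        res = coincide(stats)
        assert (res.side, res.case_id) == ("left", 1)

    def test_case2_small_difference_merges_into_majority(self):
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        # minority: right-lower-inner darker by a sub-threshold margin
        stats[("right", "lower", "inner")] = 98.0
        stats[("left", "lower", "inner")] = 100.0
        res = coincide(stats, delta=4.0)
        assert (res.side, res.case_id) == ("left", 2)
        assert any("merged" in step for step in res.trace)

    def test_case2_large_difference_flags_dissimilar_majority_wins(self):
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        stats[("right", "lower", "inner")] = 80.0
        stats[("left", "lower", "inner")] = 100.0
        res = coincide(stats, delta=4.0)
        assert (res.side, res.case_id) == ("left", 2)
        assert any("dissimilar" in step for step in res.trace)

    def test_case2_boundary_difference_counts_as_dissimilar(self):
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        stats[("right", "lower", "inner")] = 96.0
        stats[("left", "lower", "inner")] = 100.0
        res = coincide(stats, delta=4.0)
        assert any("dissimilar" in step for step in res.trace)

    def test_case3_aligned_by_half_larger_difference_wins(self):
        # upper positions darker on the right by 10, lower darker on the
        # left by 3: the upper (larger-difference) duo's side wins
        stats = stats_from({})
        for z in ("outer", "inner"):
            stats[("right", "upper", z)] = 90.0
            stats[("left", "upper", z)] = 100.0
            stats[("left", "lower", z)] = 97.0
            stats[("right", "lower", z)] = 100.0
        res = coincide(stats, delta=4.0)
        assert (res.side, res.case_id) == ("right", 3)

    def test_case3_aligned_by_zone(self):
        stats = stats_from({})
        for h in ("upper", "lower"):
            stats[("right", h, "outer")] = 88.0   # outer duo right, diff 12
            stats[("left", h, "outer")] = 100.0
            stats[("left", h, "inner")] = 98.0    # inner duo left, diff 2
            stats[("right", h, "inner")] = 100.0
        res = coincide(stats, delta=4.0)
        assert (res.side, res.case_id) == ("right", 3)

    def test_case3_diagonal_split_uses_half_differences(self):
        # left darker in upper-outer, right darker in upper-inner (diagonal
        # with lower half): upper half left-right difference dominates
        stats = stats_from({})
        stats[("left", "upper", "outer")] = 80.0    # strong left signal
        stats[("right", "upper", "inner")] = 99.0
        stats[("left", "upper", "inner")] = 100.0
        stats[("right", "lower", "outer")] = 99.0
        stats[("left", "lower", "inner")] = 98.0
        res = coincide(stats, delta=4.0)
        assert res.case_id == 3
        assert res.side == "left"

    def test_translation_invariance(self, rng):
        for _ in range(50):
            base = {key: float(v) for key, v in
                    zip(REGION_KEYS, rng.uniform(50, 200, size=8))}
            shifted = {k: v + 17.3 for k, v in base.items()}
            assert coincide(base).side == coincide(shifted).side
            assert coincide(base).case_id == coincide(shifted).case_id

    def test_mirror_antisymmetry(self, rng):
        flip = {"left": "right", "right": "left"}
        for _ in range(300):
            stats = {key: float(v) for key, v in
                     zip(REGION_KEYS, rng.uniform(0, 255, size=8))}
            res = coincide(stats)
            res_m = coincide(mirror_stats(stats))
            assert res_m.side == flip[res.side]
            assert res_m.case_id == res.case_id

    def test_terminates_with_side_and_trace_on_coarse_grid(self, rng):
        grid = np.arange(0.0, 22.0, 2.0)
        for _ in range(20000):
            stats = {key: float(rng.choice(grid)) for key in REGION_KEYS}
            res = coincide(stats)
            assert res.side in ("left", "right")
            assert res.case_id in (1, 2, 3)
            assert len(res.trace) >= 2

    def test_missing_region_rejected(self):
        stats = stats_from({})
        del stats[("left", "upper", "outer")]
        with pytest.raises(InputError):
            coincide(stats)

    def test_report_serialization_round_trips(self):
        import json
        stats = stats_from({("left", h, z): 90.0 for h, z in POSITIONS})
        payload = json.dumps(coincide(stats).to_dict())
        assert json.loads(payload)["side"] == "left"
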