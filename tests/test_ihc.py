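"""Tile entropy QC, segmentation, size binning, density selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainaging import ihc, synthetic
from brainaging.ihc import (
    SegmentationParams,
    bin_by_area,
    bin_label,
    classify_density,
    compute_tile_entropy,
    filter_tiles_by_entropy,
    rank_tiles_by_density,
    segment_cells,
    summarize_case,
    tile_stats,
)


class TestEntropy:
    def test_constant_image_zero_bits(self):
        tile = np.full((20, 20, 3), 128, dtype=np.uint8)
        assert compute_tile_entropy(tile) == 0.0

    def test_two_equal_levels_one_bit(self):
        tile = np.zeros((2, 2, 3), dtype=np.uint8)
        tile[0] = 255
        assert compute_tile_entropy(tile) == pytest.approx(1.0)

    def test_uniform_histogram_eight_bits(self):
        levels = np.arange(256, dtype=np.uint8).reshape(16, 16)
        tile = np.stack([levels] * 3, axis=-1)
        assert compute_tile_entropy(tile) == pytest.approx(8.0)

    def test_entropy_bounded_on_random_tiles(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 256, (30, 30, 3), dtype=np.uint8)
        assert 0 <= compute_tile_entropy(tile) <= 8

    def test_filter_is_strict(self):
        keep = filter_tiles_by_entropy([4.9, 5.0, 5.1], min_entropy=5)
        assert keep.tolist() == [False, False, True]


class TestSegmentation:
    def test_blank_tile_gives_no_objects(self):
        cfg = synthetic.TileConfig(width=200, height=150, n_stained=0,
                                   n_counterstained=0, seed=0)
        img, _ = synthetic.generate_tile(cfg)
        assert segment_cells(img) == []

    def test_counts_match_ground_truth_on_disjoint_disks(self):
        cfg = synthetic.TileConfig(
            n_stained=10, n_counterstained=15, radius_range=(20, 20), seed=1
        )
        img, truth = synthetic.generate_tile(cfg)
        objects = segment_cells(img)
        counts = {
            "stained": sum(o.stain_class == "stained" for o in objects),
            "counterstained": sum(o.stain_class == "other" for o in objects),
        }
        assert counts == truth.counts

    def test_single_disk_area_close_to_circle(self):
        cfg = synthetic.TileConfig(
            width=200, height=200, n_stained=1, n_counterstained=0,
            radius_range=(30, 30), seed=2,
        )
        img, _ = synthetic.generate_tile(cfg)
        objects = segment_cells(img)
        assert len(objects) == 1
        r = 30
        assert abs(objects[0].area - np.pi * r**2) <= 2 * np.pi * r

    def test_centroid_near_truth(self):
        cfg = synthetic.TileConfig(
            width=300, height=200, n_stained=1, n_counterstained=0,
            radius_range=(15, 15), seed=3,
        )
        img, truth = synthetic.generate_tile(cfg)
        obj = segment_cells(img)[0]
        assert abs(obj.x - truth.objects.x[0]) < 2
        assert abs(obj.y - truth.objects.y[0]) < 2

    def test_min_area_filters_small_components(self):
        cfg = synthetic.TileConfig(
            width=300, height=200, n_stained=4, n_counterstained=0,
            radius_range=(6, 6), seed=4,
        )
        img, _ = synthetic.generate_tile(cfg)
        big = segment_cells(img, SegmentationParams(min_area=500))
        assert big == []

    def test_hed_mode_agrees_on_clean_disks(self):
        cfg = synthetic.TileConfig(n_stained=8, n_counterstained=8,
                                   radius_range=(15, 20), seed=5)
        img, truth = synthetic.generate_tile(cfg)
        objects = segment_cells(img, SegmentationParams(mode="hed"))
        stained = sum(o.stain_class == "stained" for o in objects)
        assert stained == truth.counts["stained"]
        assert len(objects) - stained == truth.counts["counterstained"]

    def test_conservation_stained_plus_other_equals_total(self, small_tile):
        img, _ = small_tile
        _, stats = tile_stats(img, "t0", "case0", "young")
        assert stats.n_stained + stats.n_other == stats.n_total


class TestSizeBins:
    @pytest.mark.parametrize(
        "area,expected",
        [(499, None), (500, "small"), (2999, "small"), (3000, "medium"),
         (5999, "medium"), (6000, "large"), (9000, "large"),
         (9001, "very_large"), (50000, "very_large")],
    )
    def test_boundaries(self, area, expected):
        assert bin_label(area) == expected

    def test_example_counts(self):
        counts = bin_by_area([600.0, 3500.0, 7000.0, 10000.0])
        assert counts == {"small": 1, "medium": 1, "large": 1, "very_large": 1}

    def test_small_areas_excluded_from_bins(self):
        counts = bin_by_area([100.0, 499.0])
        assert sum(counts.values()) == 0

    @settings(deadline=None, max_examples=200)
    @given(area=st.floats(min_value=500, max_value=1e6, allow_nan=False))
    def test_bins_partition_binned_range(self, area):
        labels = [
            label for label, lo, hi in ihc.SIZE_BINS if lo <= area < hi
        ]
        assert len(labels) == 1
        assert bin_label(area) == labels[0]


class TestDensity:
    def _tiles(self, counts, case="c1"):
        return pd.DataFrame(
            {
                "tile_id": [f"t{i:04d}" for i in range(len(counts))],
                "case_id": case,
                "age_group": "young",
                "total": counts,
            }
        )

    def test_tercile_split_on_distinct_counts(self):
        frame = classify_density(self._tiles(list(range(1, 301))), k=5)
        low = frame[frame.density_class == "low"]["total"]
        high = frame[frame.density_class == "high"]["total"]
        assert low.max() == 100 and low.min() == 1
        assert high.min() == 201 and high.max() == 300

    def test_equal_counts_split_deterministically(self):
        a = classify_density(self._tiles([7] * 30), k=3)
        b = classify_density(self._tiles([7] * 30), k=3)
        pd.testing.assert_frame_equal(a, b)
        assert (a.density_class == "low").sum() == 10
        assert (a.density_class == "high").sum() == 10

    def test_selection_of_extreme_tiles_per_case(self):
        frame = classify_density(self._tiles(list(range(1, 31))), k=5)
        chosen_low = frame[(frame.density_class == "low") & frame.selected]["total"]
        chosen_high = frame[(frame.density_class == "high") & frame.selected]["total"]
        assert sorted(chosen_low) == [1, 2, 3, 4, 5]
        assert sorted(chosen_high) == [26, 27, 28, 29, 30]

    def test_shortfall_selects_all(self):
        frame = classify_density(self._tiles(list(range(1, 13))), k=50)
        low = frame[frame.density_class == "low"]
        assert low["selected"].all()

    def test_rank_tiles_matches_full_sort(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 1000, 40).tolist()
        frame = self._tiles(counts)
        top = rank_tiles_by_density(frame, 7)
        oracle = frame.sort_values(
            ["total", "tile_id"], ascending=[False, True]
        ).head(7)
        pd.testing.assert_frame_equal(top.reset_index(drop=True),
                                      oracle.reset_index(drop=True))

    def test_rank_k1_and_k_full(self):
        frame = self._tiles([5, 9, 2])
        assert rank_tiles_by_density(frame, 1)["total"].iloc[0] == 9
        assert len(rank_tiles_by_density(frame, 99)) == 3


class TestCaseSummary:
    def _stats_frame(self):
        rows = []
        for i, (case, group) in enumerate([("c1", "young"), ("c1", "young"), ("c2", "old")]):
            rows.append(
                {
                    "tile_id": f"t{i}", "case_id": case, "age_group": group,
                    "total": 10 + i, "stained": 4, "other": 6 + i,
                    "bin_small": 2, "bin_medium": 1, "bin_large": 0,
                    "bin_very_large": 0,
                }
            )
        return pd.DataFrame(rows)

    def test_single_tile_totals_equal_tile_counts(self):
        tidy, totals = summarize_case(self._stats_frame().iloc[:1])
        total_row = totals[(totals.measure == "total")]
        assert total_row["value"].iloc[0] == 10

    def test_two_tiles_additive(self):
        tidy, totals = summarize_case(self._stats_frame().iloc[:2])
        assert totals[totals.measure == "total"]["value"].iloc[0] == 21
        assert totals[totals.measure == "other"]["value"].iloc[0] == 13

    def test_tidy_keys_present(self):
        tidy, _ = summarize_case(self._stats_frame())
        assert {"case_id", "age_group", "tile_id", "measure", "value"} <= set(tidy.columns)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_case(pd.DataFrame())
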