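"""Track statistics, hue filtering, precision/recall, speed comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hsbcyto import (
    TrackSet,
    compare_speeds,
    filter_tracks_by_hue,
    link_spots,
    precision_recall,
    track_statistics,
)


def make_tracks(positions_by_track, frame_interval_s=30.0, hues=None):
    rows = []
    for tid, positions in positions_by_track.items():
        for t, (x, y, z) in enumerate(positions):
            rows.append({
                "track_id": tid, "time_index": t,
                "x_um": x, "y_um": y, "z_um": z,
                "hue": (hues or {}).get(tid, 50.0),
            })
    return TrackSet(spots=pd.DataFrame(rows),
                    frame_interval_s=frame_interval_s)


class TestTrackStatistics:
    def test_stationary_track_has_zero_speed(self):
        ts = make_tracks({0: [(5, 5, 5)] * 5})
        stats = track_statistics(ts).track_stats
        assert stats["mean_speed_um_s"].iloc[0] == 0.0
        assert stats["n_spots"].iloc[0] == 5

    def test_straight_line_two_um_per_frame(self):
        ts = make_tracks({0: [(2 * t, 0, 0) for t in range(6)]},
                         frame_interval_s=30.0)
        stats = track_statistics(ts).track_stats
        assert stats["mean_speed_um_s"].iloc[0] == pytest.approx(2 / 30)

    def test_constant_hue_median(self):
        ts = make_tracks({0: [(0, 0, 0)] * 4}, hues={0: 120.0})
        stats = track_statistics(ts).track_stats
        assert stats["hue_median"].iloc[0] == 120.0

    def test_single_spot_track_speed_missing(self):
        ts = make_tracks({0: [(1, 1, 1)], 1: [(0, 0, 0), (3, 0, 0)]})
        stats = track_statistics(ts).track_stats.set_index("track_id")
        assert np.isnan(stats.loc[0, "mean_speed_um_s"])
        assert stats.loc[1, "mean_speed_um_s"] == pytest.approx(3 / 30)

    def test_time_gap_divides_by_elapsed_time(self):
        spots = pd.DataFrame({
            "track_id": [0, 0], "time_index": [0, 3],
            "x_um": [0.0, 9.0], "y_um": [0.0, 0.0], "z_um": [0.0, 0.0],
        })
        ts = TrackSet(spots=spots, frame_interval_s=10.0)
        stats = track_statistics(ts).track_stats
        assert stats["mean_speed_um_s"].iloc[0] == pytest.approx(9 / 30)

    def test_speed_invariant_to_translation_and_time_reversal(self, rng):
        pos = np.cumsum(rng.normal(0, 2, size=(8, 3)), axis=0)
        ts = make_tracks({0: [tuple(p) for p in pos]})
        base = track_statistics(ts).track_stats["mean_speed_um_s"].iloc[0]
        shifted = make_tracks({0: [tuple(p + 100) for p in pos]})
        assert track_statistics(shifted).track_stats[
            "mean_speed_um_s"].iloc[0] == pytest.approx(base)
        reversed_ = make_tracks({0: [tuple(p) for p in pos[::-1]]})
        assert track_statistics(reversed_).track_stats[
            "mean_speed_um_s"].iloc[0] == pytest.approx(base)

    def test_unsorted_time_rejected(self):
        spots = pd.DataFrame({
            "track_id": [0, 0], "time_index": [2, 1],
            "x_um": [0.0, 1.0], "y_um": [0.0, 0.0], "z_um": [0.0, 0.0],
        })
        with pytest.raises(ValueError, match="increasing"):
            TrackSet(spots=spots, frame_interval_s=1.0)


class TestHueFilter:
    def test_single_interval_catches_all(self):
        ts = make_tracks({i: [(0, 0, 0)] * 3 for i in range(4)},
                         hues={i: 40.0 + i for i in range(4)})
        out = filter_tracks_by_hue(ts, [("neutrophil", (30, 60))])
        assert (out.track_stats["class_label"] == "neutrophil").all()

    def test_empty_class_defs_all_unclassified(self):
        ts = make_tracks({0: [(0, 0, 0)] * 3})
        out = filter_tracks_by_hue(ts, [])
        assert (out.track_stats["class_label"] == "unclassified").all()

    def test_first_matching_interval_wins(self):
        ts = make_tracks({0: [(0, 0, 0)] * 3}, hues={0: 45.0})
        out = filter_tracks_by_hue(ts, [("a", (40, 50)), ("b", (30, 60))])
        assert out.track_stats["class_label"].iloc[0] == "a"

    def test_circular_interval(self):
        ts = make_tracks({0: [(0, 0, 0)] * 3, 1: [(0, 0, 0)] * 3},
                         hues={0: 250.0, 1: 5.0})
        out = filter_tracks_by_hue(ts, [("red", (240, 10))])
        assert (out.track_stats["class_label"] == "red").all()


class TestPrecisionRecall:
    def test_perfect_prediction(self):
        labels = pd.Series(["a", "a", "b"], index=[0, 1, 2])
        report = precision_recall(labels, labels)
        assert report.precision("a") == 1.0
        assert report.recall("b") == 1.0

    def test_counting_example(self):
        truth = pd.Series(["A", "A", "A", "B"], index=range(4))
        pred = pd.Series(["A", "A", "B", "B"], index=range(4))
        report = precision_recall(pred, truth)
        row = report.per_class.loc["A"]
        assert (row["true_positives"], row["false_positives"],
                row["false_negatives"]) == (2, 0, 1)
        assert report.precision("A") == 1.0
        assert report.recall("A") == pytest.approx(2 / 3)

    def test_fp_only_class_has_undefined_recall(self):
        truth = pd.Series(["A", "A"], index=[0, 1])
        pred = pd.Series(["A", "C"], index=[0, 1])
        report = precision_recall(pred, truth)
        row = report.per_class.loc["C"]
        assert not row["recall_defined"]
        assert np.isnan(row["recall"])
        assert row["false_positives"] == 1

    def test_undefined_precision_flagged_not_zero(self):
        truth = pd.Series(["A", "B"], index=[0, 1])
        pred = pd.Series(["B", "B"], index=[0, 1])
        report = precision_recall(pred, truth)
        assert np.isnan(report.precision("A"))
        assert not report.per_class.loc["A", "precision_defined"]

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="same track ids"):
            precision_recall(pd.Series(["a"], index=[0]),
                             pd.Series(["a"], index=[1]))


class TestCompareSpeeds:
    def test_identical_groups(self):
        res = compare_speeds([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_shifted_groups_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = compare_speeds(a, b)
        # pooled t by hand: diff -1, sp² = 1, se = sqrt(2/3)
        se = np.sqrt(2 / 3)
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.t_statistic == pytest.approx(-1.0 / se)
        tcrit = sps.t.ppf(0.975, 4)
        assert res.ci_low == pytest.approx(-1 - tcrit * se)
        assert res.ci_high == pytest.approx(-1 + tcrit * se)
        # CI symmetric about the difference
        assert (res.ci_low + res.ci_high) / 2 == pytest.approx(-1.0)

    def test_ci_excludes_zero_iff_significant(self, rng):
        for shift in (0.0, 5.0):
            a = rng.normal(0, 1, 30)
            b = rng.normal(shift, 1, 30)
            res = compare_speeds(a, b)
            excludes = res.ci_low > 0 or res.ci_high < 0
            assert excludes == (res.p_value < 0.05)

    def test_welch_variant_differs_under_heteroscedasticity(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(1, 3.0, 50)
        pooled = compare_speeds(a, b)
        welch = compare_speeds(a, b, welch=True)
        assert welch.df < pooled.df

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_speeds([1.0], [1.0, 2.0])


class TestLinker:
    def test_links_well_separated_walkers(self, rng):
        truth = {}
        rows = []
        for tid in range(3):
            origin = np.array([100.0 * tid, 0.0, 0.0])
            pos = origin + np.cumsum(rng.normal(0, 1.0, (5, 3)), axis=0)
            truth[tid] = pos
            for t, p in enumerate(pos):
                rows.append({"time_index": t, "x_um": p[0], "y_um": p[1],
                             "z_um": p[2]})
        spots = pd.DataFrame(rows)
        linked = link_spots(spots, max_step_um=20.0, frame_interval_s=30.0)
        # 3 tracks of 5 spots each
        sizes = linked.spots.groupby("track_id").size()
        assert sorted(sizes) == [5, 5, 5]
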