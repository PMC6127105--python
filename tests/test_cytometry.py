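"""Gating, hue/saturation classification, and channel-count accounting."""

from itertools import combinations

import pandas as pd
import pytest

from hsbcyto import (
    Gate,
    apply_gates,
    classify_by_hue_saturation,
    colocalization_channel_count,
    expected_hue,
    traditional_channel_count,
)


class TestChannelCounts:
    @pytest.mark.parametrize("n, expected", [(1, 1), (3, 7), (6, 63)])
    def test_traditional_matches_subset_enumeration(self, n, expected):
        assert traditional_channel_count(n) == expected
        # independent oracle: enumerate non-empty subsets
        subsets = [c for k in range(1, n + 1)
                   for c in combinations(range(n), k)]
        assert len(subsets) == expected

    @pytest.mark.parametrize("n, expected", [(2, 1), (3, 4), (4, 11)])
    def test_colocalization_counts_order_two_plus(self, n, expected):
        assert colocalization_channel_count(n) == expected
        subsets = [c for k in range(2, n + 1)
                   for c in combinations(range(n), k)]
        assert len(subsets) == expected

    @pytest.mark.parametrize("n", range(2, 10))
    def test_difference_is_single_positive_channels(self, n):
        assert (traditional_channel_count(n)
                - colocalization_channel_count(n)) == n

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            traditional_channel_count(0)
        with pytest.raises(ValueError):
            colocalization_channel_count(1)


class TestApplyGates:
    @pytest.fixture
    def events(self, rng):
        return pd.DataFrame({
            "hue_median": rng.uniform(0, 256, 200),
            "brightness_median": rng.uniform(0, 256, 200),
        })

    def test_full_range_gate_catches_all(self, events):
        g = Gate("all", {"hue_median": (0, 256)})
        labels = apply_gates(events, [g]).labels
        assert (labels == "all").all()

    def test_circular_hue_gate_wraps_through_zero(self):
        events = pd.DataFrame({"hue_median": [0.0, 5.0, 250.0, 100.0]})
        g = Gate("red", {"hue_median": (245, 10)})
        labels = apply_gates(events, [g]).labels
        assert list(labels) == ["red", "red", "red", "ungated"]

    def test_hierarchy_assigns_deepest_gate(self, events):
        parent = Gate("bright", {"brightness_median": (128, 256)})
        child = Gate("bright_red", {"hue_median": (0, 50)}, parent="bright")
        labels = apply_gates(events, [parent, child]).labels
        in_parent = events["brightness_median"] >= 128
        in_child = in_parent & (events["hue_median"] <= 50)
        assert (labels[in_child] == "bright_red").all()
        assert (labels[in_parent & ~in_child] == "bright").all()
        assert (labels[~in_parent] == "ungated").all()

    def test_overlapping_siblings_first_listed_wins(self):
        events = pd.DataFrame({"hue_median": [40.0]})
        a = Gate("a", {"hue_median": (0, 100)})
        b = Gate("b", {"hue_median": (20, 60)})
        assert apply_gates(events, [a, b]).labels.iloc[0] == "a"
        assert apply_gates(events, [b, a]).labels.iloc[0] == "b"

    def test_counts_invariant_under_event_permutation(self, events, rng):
        g = [Gate("lo", {"hue_median": (0, 85)}),
             Gate("hi", {"hue_median": (86, 256)})]
        direct = apply_gates(events, g).counts()
        shuffled = events.sample(frac=1.0, random_state=0)
        assert apply_gates(shuffled, g).counts().to_dict() == direct.to_dict()

    def test_quadrant_percentages_sum_to_100(self, events):
        gates = [
            Gate("q1", {"hue_median": (0, 128), "brightness_median": (0, 128)}),
            Gate("q2", {"hue_median": (0, 128),
                        "brightness_median": (128.001, 256)}),
            Gate("q3", {"hue_median": (128.001, 256),
                        "brightness_median": (0, 128)}),
            Gate("q4", {"hue_median": (128.001, 256),
                        "brightness_median": (128.001, 256)}),
        ]
        pct = apply_gates(events, gates).percentages()
        assert pct.sum() == pytest.approx(100.0)

    def test_unknown_column_rejected(self, events):
        with pytest.raises(KeyError, match="nope"):
            apply_gates(events, [Gate("g", {"nope": (0, 1)})])

    def test_unknown_parent_and_cycles_rejected(self, events):
        with pytest.raises(ValueError, match="parent"):
            apply_gates(events, [Gate("g", {"hue_median": (0, 1)},
                                      parent="ghost")])
        a = Gate("a", {"hue_median": (0, 1)}, parent="b")
        b = Gate("b", {"hue_median": (0, 1)}, parent="a")
        with pytest.raises(ValueError, match="cycle"):
            apply_gates(events, [a, b])


class TestClassifyByHueSaturation:
    def events_for(self, combos):
        rows = []
        for combo in combos:
            hue = expected_hue(combo)
            rows.append({
                "hue_median": 0.0 if hue == "achromatic" else float(hue),
                "saturation_median": 230.0 if len(combo) == 3 else 0.0,
            })
        return pd.DataFrame(rows)

    def test_pure_green_cells_assigned_to_green(self):
        events = self.events_for([{"G"}] * 5)
        labels = classify_by_hue_saturation(events, ("R", "G", "B"),
                                            sat_threshold=204).labels
        assert (labels == "G+").all()

    def test_equal_rgb_cells_are_triple_positive(self):
        events = pd.DataFrame({
            "hue_median": [0.0, 3.0],
            "saturation_median": [255.0, 250.0],
        })
        labels = classify_by_hue_saturation(events, ("R", "G", "B"),
                                            sat_threshold=0.8 * 256).labels
        assert (labels == "R+G+B+").all()

    def test_all_seven_combinations_recovered(self):
        combos = [{"R"}, {"G"}, {"B"}, {"R", "G"}, {"G", "B"}, {"R", "B"},
                  {"R", "G", "B"}]
        events = self.events_for(combos)
        labels = classify_by_hue_saturation(events, ("R", "G", "B"),
                                            sat_threshold=204).labels
        assert list(labels) == ["R+", "G+", "B+", "R+G+", "G+B+", "R+B+",
                                "R+G+B+"]

    def test_marker_names_appear_in_labels(self):
        events = self.events_for([{"R"}, {"R", "G"}])
        labels = classify_by_hue_saturation(
            events, ("CD68", "MHCII", "DAPI"), sat_threshold=204
        ).labels
        assert list(labels) == ["CD68+", "CD68+MHCII+"]

    def test_halfway_hue_is_ungated_at_small_tolerance(self):
        # hue 21.5 sits between R (0) and RG (43)
        events = pd.DataFrame({"hue_median": [21.5],
                               "saturation_median": [0.0]})
        labels = classify_by_hue_saturation(events, sat_threshold=204,
                                            hue_tolerance=5.0).labels
        assert labels.iloc[0] == "ungated"

    def test_exact_tie_is_ungated_even_within_tolerance(self):
        events = pd.DataFrame({"hue_median": [21.5],
                               "saturation_median": [0.0]})
        labels = classify_by_hue_saturation(events, sat_threshold=204,
                                            hue_tolerance=30.0).labels
        assert labels.iloc[0] == "ungated"
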