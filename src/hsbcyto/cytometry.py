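"""Histocytometry on event tables: gates, subsets, and channel accounting.

Once every cell has one surface and one event row, subsetting happens the
flow-cytometry way: rectangular (possibly hierarchical) gates on statistics
columns, with hue gates allowed to wrap through 0 so red-centred intervals
are expressible.  ``classify_by_hue_saturation`` is the canonical 3-marker
strategy: high inverted saturation → triple-positive, otherwise the nearest
expected hue names the single/double combination.

``traditional_channel_count`` / ``colocalization_channel_count`` quantify
what the co-localization-and-masking alternative costs: one derived channel
per non-empty marker combination, i.e. 2ⁿ − 1 channels for n markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .hsb import ACHROMATIC, expected_hue

__all__ = [
    "Gate",
    "SubsetAssignment",
    "traditional_channel_count",
    "colocalization_channel_count",
    "apply_gates",
    "classify_by_hue_saturation",
    "circular_contains",
    "circular_distance",
]

UNGATED = "ungated"


def traditional_channel_count(n_markers: int) -> int:
    """Channels the co-localization workflow needs for ``n_markers`` markers.

    One channel per non-empty marker combination: 2ⁿ − 1.  Six markers
    already require 63 channels; three require 7.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return 2 ** n_markers - 1


def colocalization_channel_count(n_markers: int) -> int:
    """Derived co-localization channels only: combinations of order ≥ 2.

    2ⁿ − 1 − n; for three markers, the four double/triple channels.
    """
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    return 2 ** n_markers - 1 - n_markers


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def circular_contains(lo: float, hi: float, values: np.ndarray,
                      scale: float | None = None) -> np.ndarray:
    """Membership in [lo, hi], wrapping through 0 when lo > hi."""
    values = np.asarray(values, dtype=np.float64)
    if lo <= hi:
        return (values >= lo) & (values <= hi)
    return (values >= lo) | (values <= hi)


def circular_distance(a, b, scale: float) -> np.ndarray:
    """Shortest distance on a circle of circumference ``scale``."""
    d = np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
    d = np.mod(d, scale)
    return np.minimum(d, scale - d)


@dataclass
class Gate:
    """Named conjunction of per-column intervals, optionally hierarchical.

    ``predicates`` maps column → (lo, hi), both inclusive; an interval with
    lo > hi is circular (wraps through 0 — intended for hue columns).
    ``parent`` names the enclosing gate.
    """

    name: str
    predicates: dict[str, tuple[float, float]]
    parent: str | None = None

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(events), dtype=bool)
        for column, (lo, hi) in self.predicates.items():
            if column not in events.columns:
                raise KeyError(f"gate {self.name!r}: unknown column {column!r}")
            m &= circular_contains(lo, hi, events[column].to_numpy())
        return m


@dataclass
class SubsetAssignment:
    """Per-event subset label (a gate/class name or 'ungated')."""

    labels: pd.Series

    def counts(self) -> pd.Series:
        return self.labels.value_counts()

    def percentages(self) -> pd.Series:
        return 100.0 * self.labels.value_counts() / len(self.labels)


def _check_hierarchy(gates: list[Gate]) -> dict[str, list[Gate]]:
    by_name = {g.name: g for g in gates}
    children: dict[str, list[Gate]] = {None: []}  # type: ignore[dict-item]
    for g in gates:
        if g.parent is not None and g.parent not in by_name:
            raise ValueError(f"gate {g.name!r} has unknown parent {g.parent!r}")
        children.setdefault(g.parent, []).append(g)
    for g in gates:  # cycle check
        seen = set()
        cur = g
        while cur.parent is not None:
            if cur.parent in seen or cur.parent == g.name:
                raise ValueError(f"gate hierarchy cycle involving {g.name!r}")
            seen.add(cur.name)
            cur = by_name[cur.parent]
    return children


def apply_gates(events: pd.DataFrame, gates: list[Gate]) -> SubsetAssignment:
    """Assign each event to the deepest gate whose predicate chain holds.

    Overlapping sibling gates resolve to the first listed (deterministic,
    like a manual hierarchical gating order); events matching no root gate
    are 'ungated'.
    """
    children = _check_hierarchy(gates)
    masks = {g.name: g.mask(events) for g in gates}
    labels = np.full(len(events), UNGATED, dtype=object)

    def descend(gate_list: list[Gate], active: np.ndarray) -> None:
        remaining = active.copy()
        for g in gate_list:
            hit = remaining & masks[g.name]
            labels[hit] = g.name
            descend(children.get(g.name, []), hit)
            remaining &= ~hit  # first-listed sibling wins

    descend(children.get(None, []), np.ones(len(events), dtype=bool))
    return SubsetAssignment(labels=pd.Series(labels, index=events.index,
                                             name="subset"))


def _combination_label(combo: frozenset, marker_names: dict[str, str]) -> str:
    order = [s for s in "RGB" if s in combo]
    return "+".join(marker_names[s] for s in order) + "+"


def classify_by_hue_saturation(
    events: pd.DataFrame,
    marker_names=("R", "G", "B"),
    sat_threshold: float = 204.0,
    hue_tolerance: float | None = None,
    hue_scale: int = 256,
) -> SubsetAssignment:
    """Marker-combination calls from hue and inverted-saturation medians.

    Events with ``saturation_median >= sat_threshold`` become the
    triple-positive subset (their three intensities nearly match, which is
    what high inverted saturation measures).  Every other event is assigned
    to the single/double combination whose expected hue is nearest on the
    circle, if within ``hue_tolerance`` (default hue_scale/12 — half the
    spacing between adjacent primary/secondary hues); otherwise 'ungated'.
    The saturation threshold is applied after surfacing, so re-gating at a
    different threshold costs nothing.
    """
    if hue_tolerance is None:
        hue_tolerance = hue_scale / 12.0
    names = {slot: str(n) for slot, n in zip("RGB", marker_names)}
    combos = [frozenset(c) for k in (1, 2)
              for c in combinations("RGB", k)]
    combo_hues = np.array([expected_hue(c, hue_scale) for c in combos],
                          dtype=np.float64)
    combo_labels = [_combination_label(c, names) for c in combos]
    triple_label = _combination_label(frozenset("RGB"), names)
    assert expected_hue(frozenset("RGB"), hue_scale) == ACHROMATIC

    hue = events["hue_median"].to_numpy(dtype=np.float64)
    sat = events["saturation_median"].to_numpy(dtype=np.float64)

    dists = np.stack(
        [circular_distance(hue, h, hue_scale) for h in combo_hues], axis=1
    )
    best = dists.min(axis=1)
    # ties between two expected hues are ambiguous → ungated
    tie = (dists <= best[:, None] + 1e-9).sum(axis=1) > 1
    nearest = dists.argmin(axis=1)

    labels = np.full(len(events), UNGATED, dtype=object)
    ok = (best <= hue_tolerance) & ~tie
    labels[ok] = np.array(combo_labels, dtype=object)[nearest[ok]]
    labels[sat >= sat_threshold] = triple_label
    return SubsetAssignment(labels=pd.Series(labels, index=events.index,
                                             name="subset"))
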