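"""Time-lapse analysis: per-track statistics, hue filtering, accuracy.

A track is the trajectory of one cell through a 4D acquisition.  Each spot
carries position, time and intensities; the track's *median hue* is a robust
fingerprint of the cell's marker combination, so motile cell types with
distinct colors separate on a single scalar.  Mean speed is the average
3D step displacement over elapsed time.  ``precision_recall`` scores a hue
classification against ground-truth labels, and ``compare_speeds`` is the
classical pooled two-sample t test with a 95% CI on the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cytometry import circular_contains
from .surfaces import lower_median

__all__ = [
    "TrackSet",
    "ClassificationReport",
    "SpeedComparison",
    "track_statistics",
    "filter_tracks_by_hue",
    "precision_recall",
    "compare_speeds",
    "link_spots",
]

UNCLASSIFIED = "unclassified"


@dataclass
class TrackSet:
    """Spot table (track_id, time_index, x/y/z µm, intensities, hue, ...)
    plus derived per-track statistics once computed."""

    spots: pd.DataFrame
    frame_interval_s: float | None = None
    track_stats: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        required = {"track_id", "time_index", "x_um", "y_um", "z_um"}
        missing = required - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns {sorted(missing)}")
        g = self.spots.groupby("track_id")["time_index"]
        if (g.apply(lambda s: (np.diff(s.to_numpy()) <= 0).any())).any():
            raise ValueError(
                "time_index must be strictly increasing within each track"
            )

    @property
    def track_ids(self) -> np.ndarray:
        return self.spots["track_id"].unique()


def track_statistics(tracks: TrackSet,
                     hue_column: str = "hue") -> TrackSet:
    """Fill per-track statistics: median hue, mean speed, spot count.

    Median hue is the ordinary (linear-scale) lower median of the track's
    spot hues.  Mean speed averages |Δposition| / (Δtime_index ·
    frame_interval_s) over consecutive spot pairs; gaps in time_index are
    allowed (displacement divided by actual elapsed time).  Single-spot
    tracks get speed NaN.
    """
    if tracks.frame_interval_s is None:
        raise ValueError("frame_interval_s required to compute speeds")
    dt0 = float(tracks.frame_interval_s)
    rows = []
    for tid, grp in tracks.spots.groupby("track_id", sort=True):
        grp = grp.sort_values("time_index")
        pos = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=np.float64)
        t = grp["time_index"].to_numpy(dtype=np.float64)
        if len(grp) >= 2:
            steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            elapsed = np.diff(t) * dt0
            speed = float(np.mean(steps / elapsed))
        else:
            speed = np.nan
        row = {"track_id": tid, "n_spots": len(grp),
               "mean_speed_um_s": speed}
        if hue_column in grp.columns:
            row["hue_median"] = lower_median(grp[hue_column].to_numpy())
        rows.append(row)
    stats = pd.DataFrame(rows)
    return replace(tracks, track_stats=stats)


def filter_tracks_by_hue(tracks: TrackSet, class_defs,
                         hue_column: str = "hue") -> TrackSet:
    """Label each track by the first hue interval containing its median.

    ``class_defs`` is a list of ``(class_name, (lo, hi))`` with circular
    intervals (lo > hi wraps through 0).  Tracks matching no interval are
    'unclassified'.
    """
    ts = tracks if tracks.track_stats is not None \
        and "hue_median" in tracks.track_stats.columns \
        else track_statistics(tracks, hue_column=hue_column)
    stats = ts.track_stats.copy()
    hue = stats["hue_median"].to_numpy(dtype=np.float64)
    labels = np.full(len(stats), UNCLASSIFIED, dtype=object)
    unassigned = np.ones(len(stats), dtype=bool)
    for name, (lo, hi) in class_defs:
        hit = unassigned & circular_contains(lo, hi, hue)
        labels[hit] = name
        unassigned &= ~hit
    stats["class_label"] = labels
    return replace(ts, track_stats=stats)


@dataclass
class ClassificationReport:
    """Per-class confusion counts with precision and recall.

    Precision = TP/(TP+FP) is the likelihood that a track called a class
    truly is one; recall = TP/(TP+FN) the probability a true track is
    recovered.  An undefined ratio (empty denominator) is NaN and flagged,
    never silently 0.
    """

    per_class: pd.DataFrame

    def precision(self, cls: str) -> float:
        return float(self.per_class.loc[cls, "precision"])

    def recall(self, cls: str) -> float:
        return float(self.per_class.loc[cls, "recall"])


def precision_recall(predicted, truth) -> ClassificationReport:
    """Score predicted track labels against ground truth.

    Both arguments map track id → label (Series or dict) over the same
    track ids.  'unclassified' never forms a class of its own: a true track
    predicted 'unclassified' counts as that class's FN.
    """
    pred = pd.Series(predicted)
    true = pd.Series(truth)
    if set(pred.index) != set(true.index):
        raise ValueError("predicted and truth must cover the same track ids")
    true = true.reindex(pred.index)
    classes = sorted((set(pred.unique()) | set(true.unique()))
                     - {UNCLASSIFIED})
    rows = []
    for cls in classes:
        tp = int(((pred == cls) & (true == cls)).sum())
        fp = int(((pred == cls) & (true != cls)).sum())
        fn = int(((pred != cls) & (true == cls)).sum())
        precision = tp / (tp + fp) if tp + fp > 0 else np.nan
        recall = tp / (tp + fn) if tp + fn > 0 else np.nan
        rows.append({
            "class": cls, "true_positives": tp, "false_positives": fp,
            "false_negatives": fn, "precision": precision, "recall": recall,
            "precision_defined": tp + fp > 0, "recall_defined": tp + fn > 0,
        })
    df = pd.DataFrame(rows).set_index("class")
    return ClassificationReport(per_class=df)


class SpeedComparison(NamedTuple):
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    mean_difference: float
    df: float


def compare_speeds(group_a, group_b, welch: bool = False) -> SpeedComparison:
    """Two-tailed unpaired Student's t test on two speed samples.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.  Returns the t statistic, two-sided p, and the 95% CI on
    mean(A) − mean(B).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 finite speeds")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    diff = float(a.mean() - b.mean())
    if welch:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        se = np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    else:
        dof = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / dof
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    tcrit = sps.t.ppf(0.975, dof)
    return SpeedComparison(
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        mean_difference=diff, df=float(dof),
    )


def link_spots(spots: pd.DataFrame, max_step_um: float,
               frame_interval_s: float | None = None) -> TrackSet:
    """Greedy nearest-neighbour frame-to-frame linker (plumbing).

    Takes a spot table without track ids (columns time_index, x/y/z µm,
    intensities) and links each spot to the nearest spot of the previous
    frame within ``max_step_um``; unmatched spots start new tracks.  A
    deliberately simple linker for end-to-end synthetic runs — tracking
    quality is not this package's contribution.
    """
    df = spots.sort_values("time_index").reset_index(drop=True)
    track_of = np.full(len(df), -1, dtype=np.int64)
    next_track = 0
    prev_idx: list[int] = []
    for t in sorted(df["time_index"].unique()):
        cur_idx = df.index[df["time_index"] == t].tolist()
        if prev_idx:
            prev_pos = df.loc[prev_idx, ["x_um", "y_um", "z_um"]].to_numpy()
            cur_pos = df.loc[cur_idx, ["x_um", "y_um", "z_um"]].to_numpy()
            d = np.linalg.norm(cur_pos[:, None] - prev_pos[None], axis=2)
            used_prev: set[int] = set()
            for ci in np.argsort(d.min(axis=1)):
                order = np.argsort(d[ci])
                for pi in order:
                    if d[ci, pi] > max_step_um:
                        break
                    if pi not in used_prev:
                        track_of[cur_idx[ci]] = track_of[prev_idx[pi]]
                        used_prev.add(pi)
                        break
        for i in cur_idx:
            if track_of[i] < 0:
                track_of[i] = next_track
                next_track += 1
        prev_idx = cur_idx
    df["track_id"] = track_of
    return TrackSet(spots=df, frame_interval_s=frame_interval_s)
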