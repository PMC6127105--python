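"""Object ("surface") creation from the brightness channel, and statistics.

Because brightness = max over the three input channels, every cell positive
for any marker appears in this single channel, so one segmentation pass
yields complete objects for all marker combinations — the whole point of the
workflow.  Segmentation itself is a deliberately simple stand-in for a
commercial surface-creation tool: global/Otsu threshold, optional
distance-transform watershed to split touching cells, connected components,
small-object removal.

Per-object statistics (volume, centroid, per-channel mean/median, HSB
medians) form the event table that feeds histocytometry gating and FCS
export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .hsb import HSBImage
from .image import MultiChannelImage

__all__ = [
    "SegmentationParams",
    "SurfaceSet",
    "create_surfaces",
    "extract_statistics",
    "backgate",
    "lower_median",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def lower_median(values: np.ndarray) -> float:
    """Median taking the lower middle value for even counts.

    Deterministic and integer-preserving, so medians of integer channels
    stay on the channel scale.
    """
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("median of empty set")
    return float(v[(v.size - 1) // 2])


@dataclass
class SegmentationParams:
    """Knobs of the surface stand-in.

    ``split_touching`` runs a watershed seeded at distance-transform maxima
    smoothed at the ``seed_diameter_um`` scale — cells in tissue pack
    tightly, so it defaults on.
    """

    threshold: float | str = "otsu"
    min_voxels: int = 1
    split_touching: bool = True
    seed_diameter_um: float = 8.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.split_touching and self.seed_diameter_um <= 0:
            raise ValueError("seed_diameter_um must be > 0 when splitting")


@dataclass
class SurfaceSet:
    """Dense integer label volume (0 = background) plus its event table."""

    labels: np.ndarray
    stats: pd.DataFrame
    params: SegmentationParams
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_objects(self) -> int:
        return 0 if self.stats is None else len(self.stats)

    def object_ids(self) -> np.ndarray:
        return self.stats["object_id"].to_numpy()


def _as_volume(brightness) -> tuple[np.ndarray, tuple[float, float, float]]:
    if isinstance(brightness, MultiChannelImage):
        if brightness.n_channels != 1:
            raise ValueError(
                f"surface creation takes a single channel; got "
                f"{brightness.n_channels} (use merge/select first)"
            )
        if brightness.n_frames != 1:
            raise ValueError("surface creation operates on one time point")
        return brightness.data[0, :, 0], brightness.voxel_size_um
    vol = np.asarray(brightness)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError("expected a (Z,Y,X) or (Y,X) array")
    return vol, (1.0, 1.0, 1.0)


def create_surfaces(brightness, params: SegmentationParams | None = None,
                    voxel_size_um=None) -> SurfaceSet:
    """Segment objects from a single (brightness) channel.

    Empty foreground is a valid result with zero objects, not an error.
    Statistics beyond geometry are added with :func:`extract_statistics`.
    """
    params = params or SegmentationParams()
    vol, vox = _as_volume(brightness)
    if voxel_size_um is not None:
        vox = tuple(float(v) for v in voxel_size_um)

    if params.threshold == "otsu":
        thr = float(threshold_otsu(vol)) if vol.min() != vol.max() else \
            (np.inf if vol.max() == 0 else float(vol.max()))
    else:
        thr = float(params.threshold)
    mask = vol >= thr
    structure = _STRUCTURES[params.connectivity]

    if mask.any() and params.split_touching:
        # anisotropy-aware EDT, smoothed so each cell keeps a single maximum
        sampling = (vox[2], vox[1], vox[0])  # (z, y, x) µm
        dist = ndimage.distance_transform_edt(mask, sampling=sampling)
        sigma_um = params.seed_diameter_um / 4.0
        sigma_vox = [max(sigma_um / s, 0.5) for s in sampling]
        smooth = ndimage.gaussian_filter(dist, sigma=sigma_vox)
        min_dist_vox = max(int(round(params.seed_diameter_um / 2.0
                                     / min(sampling))), 1)
        peaks = peak_local_max(
            smooth, min_distance=min_dist_vox, labels=mask,
            exclude_border=False,
        )
        markers = np.zeros(vol.shape, dtype=np.int32)
        for k, idx in enumerate(peaks, start=1):
            markers[tuple(idx)] = k
        if markers.max() == 0:
            labels, _ = ndimage.label(mask, structure=structure)
        else:
            labels = watershed(-smooth, markers=markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask, structure=structure)

    labels = np.asarray(labels, dtype=np.int32)
    # drop small objects and relabel densely, preserving original order
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= params.min_voxels]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    labels = remap[labels]

    stats = _geometry_stats(labels, vox)
    return SurfaceSet(labels=labels, stats=stats, params=params,
                      voxel_size_um=vox)


def _geometry_stats(labels: np.ndarray, vox) -> pd.DataFrame:
    n = int(labels.max())
    ids = np.arange(1, n + 1)
    if n == 0:
        return pd.DataFrame(
            columns=["object_id", "volume_voxels",
                     "centroid_x_um", "centroid_y_um", "centroid_z_um"]
        )
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index=ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index=ids)
    cz, cy, cx = np.array(centroids).T
    return pd.DataFrame({
        "object_id": ids,
        "volume_voxels": counts.astype(int),
        "centroid_x_um": cx * vox[0],
        "centroid_y_um": cy * vox[1],
        "centroid_z_um": cz * vox[2],
    })


def extract_statistics(s: SurfaceSet, channels,
                       hsb: HSBImage | None = None) -> pd.DataFrame:
    """Per-object statistics table across named channels.

    ``channels`` maps channel name → (Z,Y,X) array (original, log-transformed
    and/or HSB channels alike); each contributes ``{name}_mean`` and
    ``{name}_median`` columns.  With ``hsb`` given, ``hue_median`` (over the
    object's voxels with brightness > 0), ``saturation_median`` and
    ``brightness_median`` columns are added.  The resulting table is also
    stored on ``s.stats``.
    """
    if isinstance(channels, dict):
        named = list(channels.items())
    else:
        named = list(channels)
    labels = s.labels
    for name, arr in named:
        arr = np.asarray(arr)
        if arr.shape != labels.shape:
            raise ValueError(
                f"channel {name!r} shape {arr.shape} does not match labels "
                f"{labels.shape}"
            )

    stats = _geometry_stats(labels, s.voxel_size_um)
    n = len(stats)
    ids = stats["object_id"].to_numpy()

    flat_labels = labels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    starts = np.searchsorted(sorted_labels, ids, side="left")
    ends = np.searchsorted(sorted_labels, ids, side="right")

    def per_object(arr: np.ndarray, reducer) -> np.ndarray:
        flat = arr.ravel()[order]
        return np.array([reducer(flat[a:b]) for a, b in zip(starts, ends)])

    for name, arr in named:
        arr = np.asarray(arr, dtype=np.float64)
        if n:
            stats[f"{name}_mean"] = per_object(arr, np.mean)
            stats[f"{name}_median"] = per_object(arr, lower_median)
        else:
            stats[f"{name}_mean"] = np.nan
            stats[f"{name}_median"] = np.nan

    if hsb is not None and n:
        hue = hsb.hue[0, :, :, :] if hsb.hue.ndim == 4 else hsb.hue
        sat = hsb.saturation_inv[0] if hsb.saturation_inv.ndim == 4 \
            else hsb.saturation_inv
        bri = hsb.brightness[0] if hsb.brightness.ndim == 4 else hsb.brightness
        flat_b = bri.ravel()[order]
        flat_h = hue.ravel()[order]

        def hue_median(a, b):
            seg_b = flat_b[a:b]
            seg_h = flat_h[a:b]
            lit = seg_b > 0
            return lower_median(seg_h[lit]) if lit.any() else 0.0

        stats["hue_median"] = [hue_median(a, b) for a, b in zip(starts, ends)]
        stats["saturation_median"] = per_object(
            np.asarray(sat, dtype=np.float64), lower_median)
        stats["brightness_median"] = per_object(
            np.asarray(bri, dtype=np.float64), lower_median)
    elif hsb is not None:
        stats["hue_median"] = np.nan
        stats["saturation_median"] = np.nan
        stats["brightness_median"] = np.nan

    s.stats = stats
    return stats


def backgate(s: SurfaceSet, ids) -> np.ndarray:
    """Label volume keeping only the given object ids (originals retained).

    The image-side half of gating: map a gated subset back onto the volume
    to see where those cells sit in the tissue.
    """
    ids = np.asarray(list(ids), dtype=np.int64)
    existing = np.unique(s.labels)
    unknown = sorted(set(ids.tolist()) - set(existing.tolist()) - {0})
    if unknown:
        raise KeyError(f"unknown object id(s): {unknown}")
    out = np.where(np.isin(s.labels, ids), s.labels, 0)
    return out.astype(s.labels.dtype)
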