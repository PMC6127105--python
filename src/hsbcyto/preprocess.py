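"""Image conditioning ahead of the HSB conversion.

Mirrors the whole-mount processing recipe: per-block background thresholding
down the z axis, log transformation, in-plane mean filtering, and merging of
channels by voxelwise maximum when more than three markers must funnel into
the three HSB input slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import MultiChannelImage

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "log_transform",
    "mean_filter",
    "merge_channels_max",
    "disc_footprint",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Background-removal settings.

    ``z_chunk`` slices share one threshold (blocks of 10 by default, the
    last block may be shorter); thresholds are Otsu per block and channel,
    or a single fixed intensity.
    """

    z_chunk: int = 10
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    mean_filter_radius_px: float = 2.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.z_chunk < 1:
            raise ValueError("z_chunk must be >= 1")
        if self.mean_filter_radius_px < 0:
            raise ValueError("mean_filter_radius_px must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required with method 'fixed'")
        if self.threshold_method == "otsu" and self.fixed_threshold is not None:
            raise ValueError("fixed_threshold only valid with method 'fixed'")


def _chunk_threshold(block: np.ndarray, cfg: PreprocessConfig) -> float:
    if cfg.threshold_method == "fixed":
        return float(cfg.fixed_threshold)
    if block.min() == block.max():
        if block.max() == 0:
            logger.warning("all-zero block under Otsu thresholding; "
                           "threshold set to 0 (no-op)")
        return 0.0
    # Otsu's split value belongs to the background (foreground is v > t),
    # while our rule zeroes v < threshold; half an intensity step up makes
    # the two conventions agree on integer data
    return float(threshold_otsu(block)) + 0.5


def subtract_background(img: MultiChannelImage,
                        cfg: PreprocessConfig | None = None) -> MultiChannelImage:
    """Zero voxels below a per-(channel, z-block) threshold.

    Voxels at or above the threshold pass through bit-identical; the output
    support is always a subset of the input support.
    """
    cfg = cfg or PreprocessConfig()
    out = img.data.copy()
    n_z = img.n_slices
    for t in range(img.n_frames):
        for c in range(img.n_channels):
            for z0 in range(0, n_z, cfg.z_chunk):
                z1 = min(z0 + cfg.z_chunk, n_z)
                block = out[t, z0:z1, c]
                thr = _chunk_threshold(block, cfg)
                block[block < thr] = 0
    return img.with_data(out)


def log_transform(img: MultiChannelImage) -> MultiChannelImage:
    """Normalized log1p, mapped back onto the channel scale.

    v → round(log(1+v) / log(1+vmax) · vmax): monotone, 0 ↦ 0 and
    vmax ↦ vmax, so downstream integer arithmetic is unchanged.
    """
    vmax = img.max_value
    lut = np.floor(
        np.log1p(np.arange(vmax + 1, dtype=np.float64)) / np.log1p(vmax) * vmax
        + 0.5
    ).astype(img.data.dtype)
    return img.with_data(lut[img.data])


def disc_footprint(radius: float) -> np.ndarray:
    """Boolean 2D disc: offsets with dx² + dy² ≤ radius²."""
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return (dx * dx + dy * dy) <= radius * radius + 1e-9


def mean_filter(img: MultiChannelImage, radius_px: float | None = None,
                three_d: bool = False) -> MultiChannelImage:
    """Mean over the disc of pixels within ``radius_px``, slice-wise.

    The footprint is the in-plane Euclidean disc (13 pixels at radius 2.0);
    borders are zero-padded.  ``three_d`` switches to a spherical footprint
    across z (isotropic in voxel units).
    """
    radius = 2.0 if radius_px is None else float(radius_px)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return img.with_data(img.data.copy())
    if three_d:
        r = int(np.floor(radius))
        dz, dy, dx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
        fp = (dx * dx + dy * dy + dz * dz) <= radius * radius + 1e-9
        kernel = fp / fp.sum()
        out = np.empty_like(img.data)
        for t in range(img.n_frames):
            for c in range(img.n_channels):
                vol = img.data[t, :, c].astype(np.float64)
                filtered = ndimage.convolve(vol, kernel, mode="constant", cval=0.0)
                out[t, :, c] = img.quantize(filtered)
        return img.with_data(out)
    fp = disc_footprint(radius)
    kernel = fp / fp.sum()
    out = np.empty_like(img.data)
    for t in range(img.n_frames):
        for z in range(img.n_slices):
            for c in range(img.n_channels):
                plane = img.data[t, z, c].astype(np.float64)
                filtered = ndimage.convolve(plane, kernel, mode="constant",
                                            cval=0.0)
                out[t, z, c] = img.quantize(filtered)
    return img.with_data(out)


def merge_channels_max(img: MultiChannelImage,
                       channel_indices) -> MultiChannelImage:
    """Voxelwise maximum of the selected channels, as one channel.

    This is the escape hatch for panels with more than three markers: merged
    channels share one HSB input slot, and their individual intensities are
    still recovered per object at statistics extraction.
    """
    indices = [img.channel_index(c) for c in channel_indices]
    if not indices:
        raise ValueError("at least one channel must be selected")
    merged = img.data[:, :, indices].max(axis=2, keepdims=True)
    name = "max(" + ",".join(img.channel_names[i] for i in indices) + ")" \
        if len(indices) > 1 else img.channel_names[indices[0]]
    return img.with_data(merged, channel_names=[name])
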