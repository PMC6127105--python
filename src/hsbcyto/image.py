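"""Dense multi-channel image container.

All images in the package share one canonical axis order, (T, Z, C, Y, X),
with singleton axes materialized.  Keeping every image five-dimensional means
no operation has to branch on dimensionality: a single confocal plane and a
multi-day time-lapse flow through the same code.

Coordinates are 0-based voxel indices internally; physical micrometres appear
only in exported statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AXES = "TZCYX"

_VALID_BIT_DEPTHS = (8, 12, 16)


def dtype_for_bit_depth(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth <= 8 else np.uint16)


@dataclass
class MultiChannelImage:
    """An unsigned-integer intensity image on axes (T, Z, C, Y, X).

    Parameters
    ----------
    data:
        5-D unsigned integer array, axes ``(T, Z, C, Y, X)``.
    voxel_size_um:
        Physical voxel size ``(x, y, z)`` in micrometres; all components > 0.
    channel_names:
        One label per entry of the C axis.
    bit_depth:
        Nominal sensor depth (8, 12 or 16).  Intensities must fit in
        ``[0, 2**bit_depth - 1]``; a 12-bit image is stored in uint16.
    frame_interval_s:
        Seconds between time points, or ``None`` for static images.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: list[str] = field(default_factory=list)
    bit_depth: int = 16
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"data must have 5 axes (T,Z,C,Y,X); got {self.data.ndim}"
            )
        if self.data.dtype.kind != "u":
            raise ValueError(f"data must be unsigned integer; got {self.data.dtype}")
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")
        if self.data.size and int(self.data.max()) > self.max_value:
            raise ValueError(
                f"intensities exceed 2**{self.bit_depth}-1 = {self.max_value}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be 3 positive components (x,y,z)")

    # -- shape helpers -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def channel_index(self, name_or_index: str | int) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            i = int(name_or_index)
            if not 0 <= i < self.n_channels:
                raise IndexError(f"channel index {i} out of range")
            return i
        try:
            return self.channel_names.index(name_or_index)
        except ValueError:
            raise KeyError(
                f"unknown channel {name_or_index!r}; have {self.channel_names}"
            ) from None

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """View of one channel, axes (T, Z, Y, X)."""
        return self.data[:, :, self.channel_index(name_or_index)]

    def select_channels(self, names_or_indices) -> "MultiChannelImage":
        idx = [self.channel_index(c) for c in names_or_indices]
        return replace(
            self,
            data=self.data[:, :, idx],
            channel_names=[self.channel_names[i] for i in idx],
        )

    def with_data(self, data: np.ndarray, channel_names=None) -> "MultiChannelImage":
        return replace(
            self,
            data=data,
            channel_names=list(channel_names) if channel_names is not None
            else list(self.channel_names),
        )

    def quantize(self, values: np.ndarray) -> np.ndarray:
        """Round and clip a float array onto this image's integer scale."""
        out = np.floor(np.asarray(values, dtype=np.float64) + 0.5)
        np.clip(out, 0, self.max_value, out=out)
        return out.astype(dtype_for_bit_depth(self.bit_depth))


def promote_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/pad an array with axes given as a subset of 'TZCYX' to 5-D."""
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise ValueError(f"axes {axes!r} does not match array of ndim {data.ndim}")
    unknown = set(axes) - set(AXES)
    if unknown:
        raise ValueError(f"unrecognized axes {sorted(unknown)} (allowed: {AXES})")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axis in {axes!r}")
    for ax in AXES:
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(data, order)
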