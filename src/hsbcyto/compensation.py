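"""Post-hoc spectral spillover compensation.

Fluorophores bleed linearly into neighbouring detector channels.  Spillover
coefficients are estimated from single-stain controls (or gated
single-positive events) as the least-squares slope through the origin of
off-channel versus own-channel intensity, collected into a matrix with unit
diagonal, and applied by solving the linear mixing model per event or voxel.
Because surfaces are created from the brightness channel, compensation can
happen *after* segmentation, on the statistics or on the image — fixing a
bad coefficient is a matter of editing a number, not redoing the surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import MultiChannelImage

__all__ = ["SpilloverMatrix", "estimate_spillover", "apply_compensation"]

logger = logging.getLogger(__name__)


@dataclass
class SpilloverMatrix:
    """C×C spillover coefficients; ``coefficients[i, j]`` is the fraction of
    channel-i signal appearing in channel j.  Diagonal is exactly 1."""

    channel_names: list[str]
    coefficients: np.ndarray
    fit_r2: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        c = len(self.channel_names)
        if self.coefficients.shape != (c, c):
            raise ValueError(
                f"coefficients must be {c}×{c}, got {self.coefficients.shape}"
            )
        if not np.allclose(np.diag(self.coefficients), 1.0):
            raise ValueError("spillover diagonal must be 1")
        if (self.coefficients < 0).any():
            raise ValueError("spillover coefficients must be >= 0")
        if abs(np.linalg.det(self.coefficients)) < 1e-12:
            raise ValueError(self._singular_message())

    def _singular_message(self) -> str:
        return (
            "spillover matrix is singular; check channels "
            + ", ".join(self.channel_names)
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.coefficients, index=self.channel_names,
            columns=self.channel_names,
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(channel_names=list(df.columns),
                   coefficients=df.to_numpy(dtype=np.float64))


def _control_matrix(data, channel_names) -> np.ndarray:
    """Events × channels float matrix from a DataFrame or ndarray control."""
    if isinstance(data, pd.DataFrame):
        cols = []
        for name in channel_names:
            if name in data.columns:
                cols.append(name)
            elif f"{name}_mean" in data.columns:
                cols.append(f"{name}_mean")
            else:
                raise KeyError(
                    f"control table lacks column {name!r} or '{name}_mean'"
                )
        return data[cols].to_numpy(dtype=np.float64)
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != len(channel_names):
        raise ValueError(
            f"control sample must be (events, {len(channel_names)})"
        )
    return arr


def estimate_spillover(controls, channel_names) -> SpilloverMatrix:
    """Fit a :class:`SpilloverMatrix` from single-stain controls.

    Parameters
    ----------
    controls:
        Iterable of ``(stain_index, sample)`` where ``sample`` is an event
        table (DataFrame with per-channel columns, raw names or
        ``{name}_mean``) or an ``(events, C)`` array of pixel values, from a
        specimen carrying only the stain of channel ``stain_index``.  Gated
        single-positive events work identically.
    channel_names:
        The C channel names, defining matrix order.

    The slope of channel-j signal against channel-i signal is fit through
    the origin (background is removed upstream), ``s[i, j] = Σxy / Σx²``,
    with a through-origin R² recorded per coefficient.  Channels without a
    control keep an identity row (with a warning).
    """
    channel_names = list(channel_names)
    c = len(channel_names)
    coeff = np.eye(c)
    r2 = np.full((c, c), np.nan)
    seen: set[int] = set()
    for stain_index, sample in controls:
        i = int(stain_index)
        if not 0 <= i < c:
            raise IndexError(f"stain index {i} out of range for {c} channels")
        seen.add(i)
        x = _control_matrix(sample, channel_names)
        own = x[:, i]
        sxx = float(own @ own)
        if sxx == 0 or (len(own) > 1 and np.ptp(own) == 0):
            raise ValueError(
                f"control for channel {channel_names[i]!r} has zero variance "
                "in its own channel"
            )
        for j in range(c):
            if j == i:
                r2[i, j] = 1.0
                continue
            y = x[:, j]
            slope = float(own @ y) / sxx
            coeff[i, j] = max(slope, 0.0)
            ss_tot = float(y @ y)
            ss_res = float(((y - slope * own) ** 2).sum())
            r2[i, j] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    missing = [channel_names[i] for i in range(c) if i not in seen]
    if missing:
        logger.warning(
            "no control for channel(s) %s; rows left as identity", missing
        )
    return SpilloverMatrix(channel_names=channel_names, coefficients=coeff,
                           fit_r2=r2)


def _unmix(S: SpilloverMatrix, observed: np.ndarray,
           clamp_negative: bool) -> np.ndarray:
    """Solve observed = Sᵀ·true per row of an (N, C) array."""
    try:
        true = np.linalg.solve(S.coefficients.T, observed.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(S._singular_message()) from exc
    if clamp_negative:
        np.maximum(true, 0.0, out=true)
    return true


def apply_compensation(S: SpilloverMatrix, data,
                       clamp_negative: bool = True):
    """Remove spillover from an image or an event table.

    For a :class:`MultiChannelImage`, every voxel's C-vector is unmixed and
    re-quantized to the image's bit depth.  For an event table (DataFrame),
    raw channel columns and ``{name}_mean`` / ``{name}_median`` statistics
    columns are unmixed in place (a new frame is returned).  Negative
    solutions are clamped to 0 unless ``clamp_negative=False``.
    """
    if isinstance(data, MultiChannelImage):
        if data.n_channels != S.n_channels:
            raise ValueError(
                f"image has {data.n_channels} channels, matrix expects "
                f"{S.n_channels}"
            )
        arr = np.moveaxis(data.data, 2, -1).astype(np.float64)
        flat = arr.reshape(-1, S.n_channels)
        true = _unmix(S, flat, clamp_negative)
        out = data.quantize(true.reshape(arr.shape))
        return data.with_data(np.moveaxis(out, -1, 2))

    if isinstance(data, pd.DataFrame):
        out = data.copy()
        for suffix in ("", "_mean", "_median"):
            cols = [f"{n}{suffix}" for n in S.channel_names]
            if all(c in out.columns for c in cols):
                obs = out[cols].to_numpy(dtype=np.float64)
                out[cols] = _unmix(S, obs, clamp_negative)
        return out

    raise TypeError(
        "apply_compensation expects a MultiChannelImage or a DataFrame"
    )
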