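"""RGB → hue / inverted-saturation / brightness conversion.

This is the heart of the workflow.  Up to three fluorescence channels are
assigned to the red, green and blue slots of an RGB triple and converted per
voxel with the standard hexcone equations, with one deliberate modification:
the saturation scale is inverted.

Per voxel with intensities (r, g, b), M = max, m = min:

* brightness  B = M — any voxel positive for any marker is captured, so one
  channel suffices for surface creation of every cell;
* inverted saturation S' = m / M (0 when M = 0) — a triple-positive (white)
  voxel scores maximal, a single- or double-positive voxel scores 0, and
  pure black stays 0, so white cells stand out against background;
* hue H — the hexcone angle, mapped from [0°, 360°) to the integer scale
  [0, hue_scale); achromatic voxels (M = m) take hue 0 by convention.

Hue encodes which one or two markers dominate, independent of brightness;
triple-positives are not hue-resolvable and are instead identified by
thresholding the inverted saturation downstream.

Rounding is half-away-from-zero throughout so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import MultiChannelImage

__all__ = [
    "HSBImage",
    "HueLUT",
    "rgb_to_hsb",
    "hsb_from_arrays",
    "expected_hue",
    "make_hue_lut",
]

ACHROMATIC = "achromatic"

# hexcone angles (degrees) of equal-intensity marker mixtures
_COMBINATION_DEGREES = {
    frozenset("R"): 0.0,
    frozenset("G"): 120.0,
    frozenset("B"): 240.0,
    frozenset("RG"): 60.0,
    frozenset("GB"): 180.0,
    frozenset("RB"): 300.0,
}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # all quantities here are >= 0, so this is round-half-away-from-zero
    return np.floor(np.asarray(x) + 0.5)


@dataclass
class HSBImage:
    """Aligned hue / inverted-saturation / brightness channels.

    ``hue`` lives on the circular integer scale ``[0, hue_scale)``;
    ``saturation_inv`` on ``[0, s_scale)``; ``brightness`` on the source
    channel scale.  ``source_channels`` records which input channel was
    assigned to each of the (R, G, B) slots.
    """

    hue: np.ndarray
    saturation_inv: np.ndarray
    brightness: np.ndarray
    hue_scale: int = 256
    s_scale: int = 256
    source_channels: tuple[str, str, str] = ("R", "G", "B")
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval_s: float | None = None
    provenance: dict = field(default_factory=dict)

    def named_channels(self) -> dict[str, np.ndarray]:
        return {
            "hue": self.hue,
            "saturation_inv": self.saturation_inv,
            "brightness": self.brightness,
        }

    def to_image(self, bit_depth: int = 8) -> MultiChannelImage:
        """Pack H/S'/B into a 3-channel MultiChannelImage for export."""
        stack = np.stack(
            [self.hue, self.saturation_inv, self.brightness], axis=2
        )
        return MultiChannelImage(
            data=stack.astype(np.uint8 if bit_depth <= 8 else np.uint16),
            voxel_size_um=self.voxel_size_um,
            channel_names=["hue", "saturation_inv", "brightness"],
            bit_depth=bit_depth,
            frame_interval_s=self.frame_interval_s,
        )


def hsb_from_arrays(r, g, b, hue_scale: int = 256, s_scale: int = 256):
    """Vectorized hexcone conversion on raw arrays.

    Returns ``(hue, saturation_inv, brightness)`` as float64 arrays holding
    exact integers; callers cast to their preferred dtype.
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    M = np.maximum(np.maximum(r, g), b)
    m = np.minimum(np.minimum(r, g), b)
    delta = M - m

    brightness = M

    # multiply before dividing: m·(s_scale−1) is an exact integer, so the
    # single division is correctly rounded and exact halves round reliably
    with np.errstate(divide="ignore", invalid="ignore"):
        sat_scaled = np.where(M > 0, m * float(s_scale - 1) / np.where(M > 0, M, 1.0), 0.0)
    saturation_inv = _round_half_up(sat_scaled)

    chromatic = delta > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        h_r = np.mod((g - b) / delta, 6.0)
        h_g = (b - r) / delta + 2.0
        h_b = (r - g) / delta + 4.0
    hprime = np.where(M == r, h_r, np.where(M == g, h_g, h_b))
    degrees = np.where(chromatic, hprime * 60.0, 0.0)
    hue = np.mod(_round_half_up(degrees / 360.0 * hue_scale), hue_scale)
    hue = np.where(chromatic, hue, 0.0)
    return hue, saturation_inv, brightness


def rgb_to_hsb(img: MultiChannelImage, channels=None, hue_scale: int = 256,
               s_scale: int = 256) -> HSBImage:
    """Convert three channels of ``img`` into an :class:`HSBImage`.

    ``channels`` names (or indexes) the channels taking the R, G and B slots,
    in that order; defaults to the image's three channels as stored.
    Exactly three channels are required — merge extras first with
    :func:`hsbcyto.preprocess.merge_channels_max`.
    """
    if channels is None:
        if img.n_channels != 3:
            raise ValueError(
                f"image has {img.n_channels} channels; the HSB conversion "
                "takes exactly 3 — merge channels first with "
                "merge_channels_max, or pass channels=(r, g, b)"
            )
        channels = list(range(3))
    channels = list(channels)
    if len(channels) != 3:
        raise ValueError(
            f"exactly 3 channels must be selected, got {len(channels)}; "
            "merge extras with merge_channels_max first"
        )
    idx = [img.channel_index(c) for c in channels]
    r, g, b = (img.data[:, :, i] for i in idx)
    hue, sat_inv, brightness = hsb_from_arrays(r, g, b, hue_scale, s_scale)

    hue_dtype = np.uint8 if hue_scale <= 256 else np.uint16
    s_dtype = np.uint8 if s_scale <= 256 else np.uint16
    return HSBImage(
        hue=hue.astype(hue_dtype),
        saturation_inv=sat_inv.astype(s_dtype),
        brightness=brightness.astype(img.data.dtype),
        hue_scale=hue_scale,
        s_scale=s_scale,
        source_channels=tuple(img.channel_names[i] for i in idx),
        voxel_size_um=img.voxel_size_um,
        frame_interval_s=img.frame_interval_s,
        provenance={
            "transform": "hexcone-inverted-saturation",
            "bit_depth": img.bit_depth,
        },
    )


def expected_hue(combination, hue_scale: int = 256):
    """Hue of an equal-intensity mixture of the given marker slots.

    ``combination`` is a non-empty subset of ``{"R", "G", "B"}``.  The full
    triple returns :data:`ACHROMATIC` — equal R=G=B carries no hue, which is
    exactly why triple-positive cells are found via saturation instead.
    """
    combo = frozenset(str(c).upper() for c in combination)
    if not combo:
        raise ValueError("combination must be a non-empty subset of {R,G,B}")
    if not combo <= set("RGB"):
        raise ValueError(f"unknown markers {sorted(combo - set('RGB'))}")
    if combo == frozenset("RGB"):
        return ACHROMATIC
    degrees = _COMBINATION_DEGREES[combo]
    return int(_round_half_up(degrees / 360.0 * hue_scale)) % hue_scale


@dataclass
class HueLUT:
    """Display LUT tracing the color wheel: entry h renders pure hue h."""

    table: np.ndarray  # (hue_scale, 3) uint8
    hue_scale: int

    def __getitem__(self, h: int) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.table[h])

    def write_imagej_lut(self, path) -> None:
        """ImageJ .lut binary: 256 reds, 256 greens, 256 blues."""
        t = self.table
        if self.hue_scale != 256:
            pos = np.linspace(0, self.hue_scale - 1, 256)
            t = np.stack(
                [np.interp(pos, np.arange(self.hue_scale), t[:, c])
                 for c in range(3)], axis=1
            )
            t = _round_half_up(t).astype(np.uint8)
        Path(path).write_bytes(t.T.astype(np.uint8).tobytes())

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hue\tred\tgreen\tblue\n")
            for h, (r, g, b) in enumerate(self.table):
                fh.write(f"{h}\t{r}\t{g}\t{b}\n")


def make_hue_lut(hue_scale: int = 256) -> HueLUT:
    """Build the hue LUT: entry h is pure hue h at full brightness.

    Constructed so that converting entry h back through the hexcone recovers
    hue h exactly for every entry (max channel pinned at 255, min at 0, the
    intermediate channel quantized — the quantization error stays below half
    a hue step for any hue_scale ≤ 256·6).
    """
    if hue_scale < 2:
        raise ValueError("hue_scale must be >= 2")
    h = np.arange(hue_scale, dtype=np.float64)
    degrees = h / hue_scale * 360.0
    hp = degrees / 60.0
    sector = np.floor(hp).astype(int) % 6
    frac = hp - np.floor(hp)
    x_up = _round_half_up(frac * 255.0)       # rising intermediate channel
    x_dn = _round_half_up((1.0 - frac) * 255.0)
    full = np.full(hue_scale, 255.0)
    zero = np.zeros(hue_scale)
    # per sector: (R,G,B) = (255,x,0) (x,255,0) (0,255,x) (0,x,255) (x,0,255) (255,0,x)
    r = np.choose(sector, [full, x_dn, zero, zero, x_up, full])
    g = np.choose(sector, [x_up, full, full, x_dn, zero, zero])
    b = np.choose(sector, [zero, zero, x_up, full, full, x_dn])
    table = np.stack([r, g, b], axis=1).astype(np.uint8)
    return HueLUT(table=table, hue_scale=hue_scale)
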