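"""File formats: ImageJ-hyperstack TIFF, CSV spot/track tables, FCS 3.1.

The TIFF layer leans on :mod:`tifffile` and stores package metadata (channel
names, voxel size, bit depth) in the ImageJ ``Info`` property as JSON, so a
written stack opens normally in ImageJ/Fiji and round-trips bit-exactly here.

The FCS 3.1 writer is implemented from the published standard: HEADER with
ASCII segment offsets, a delimited TEXT segment, and a DATA segment of
little-endian single-precision floats in list mode.  ``read_fcs`` is a
minimal reader sufficient for verification and re-import of our own files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import AXES, MultiChannelImage, promote_axes

__all__ = [
    "read_image",
    "write_image",
    "write_fcs",
    "read_fcs",
    "read_tracks",
    "write_tracks",
    "read_events",
    "write_events",
]

TRACK_REQUIRED_COLUMNS = ("time_index", "track_id", "x_um", "y_um", "z_um")


# ---------------------------------------------------------------------------
# TIFF images
# ---------------------------------------------------------------------------

def write_image(img: MultiChannelImage, path) -> None:
    """Write an ImageJ-hyperstack-compatible TIFF."""
    info = {
        "channel_names": list(img.channel_names),
        "voxel_size_um": list(img.voxel_size_um),
        "bit_depth": img.bit_depth,
    }
    if img.frame_interval_s is not None:
        info["frame_interval_s"] = img.frame_interval_s
    metadata = {
        "axes": AXES,
        "Info": json.dumps(info),
        "spacing": img.voxel_size_um[2],
        "unit": "um",
    }
    if img.frame_interval_s is not None:
        metadata["finterval"] = img.frame_interval_s
    tifffile.imwrite(
        str(path),
        img.data,
        imagej=True,
        metadata=metadata,
        resolution=(1.0 / img.voxel_size_um[0], 1.0 / img.voxel_size_um[1]),
    )


def read_image(path, axis_hint: str | None = None) -> MultiChannelImage:
    """Read a TIFF / ImageJ hyperstack into canonical (T,Z,C,Y,X) form.

    ``axis_hint`` (e.g. ``"ZCYX"``) overrides the axis order when the file
    carries none; without metadata or a hint an ambiguous stack is an error
    rather than a guess.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(str(path))
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise OSError(f"cannot read {path} as TIFF: {exc}") from exc
    with tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C")
        if axis_hint:
            axes = axis_hint.upper()
        if len(axes) != data.ndim:
            raise ValueError(
                f"axis order {axes!r} does not match data of ndim {data.ndim}"
            )
        unknown = [a for a in axes if a not in AXES]
        if unknown:
            raise ValueError(
                f"{path}: ambiguous axes {series.axes!r} (unmapped {unknown}); "
                f"pass axis_hint with letters from {AXES!r}"
            )
        data = promote_axes(data, axes)
        if data.dtype.kind == "i":
            data = data.astype(np.uint16)
        if data.dtype.kind != "u":
            raise ValueError(f"{path}: unsupported dtype {data.dtype}")

        info = {}
        ij = tf.imagej_metadata or {}
        if "Info" in ij:
            try:
                info = json.loads(ij["Info"])
            except (json.JSONDecodeError, TypeError):
                info = {}
        voxel = info.get("voxel_size_um")
        if voxel is None:
            voxel = [1.0, 1.0, float(ij.get("spacing", 1.0)) or 1.0]
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if xres is not None and xres.value[0]:
                voxel[0] = xres.value[1] / xres.value[0]
            if yres is not None and yres.value[0]:
                voxel[1] = yres.value[1] / yres.value[0]
        bit_depth = info.get("bit_depth", 8 if data.dtype.itemsize == 1 else 16)
        frame_interval = info.get("frame_interval_s", ij.get("finterval"))
        names = info.get("channel_names") or [
            f"ch{i}" for i in range(data.shape[2])
        ]
    return MultiChannelImage(
        data=data,
        voxel_size_um=tuple(voxel),
        channel_names=list(names),
        bit_depth=int(bit_depth),
        frame_interval_s=None if frame_interval is None else float(frame_interval),
    )


# ---------------------------------------------------------------------------
# FCS 3.1
# ---------------------------------------------------------------------------

_DELIM = "/"


def _fcs_text(pairs: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in pairs.items():
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(events: pd.DataFrame, path, parameters=None,
              spillover=None) -> None:
    """Write an event table as an FCS 3.1 file (list mode, float32 LE).

    ``parameters`` selects the columns exported as FCS parameters (defaults
    to every numeric column).  ``spillover``, if given, is a
    :class:`~hsbcyto.compensation.SpilloverMatrix` emitted as the $SPILLOVER
    keyword.
    """
    if parameters is None:
        parameters = [c for c in events.columns
                      if pd.api.types.is_numeric_dtype(events[c])]
    parameters = list(parameters)
    if len(events) == 0:
        raise ValueError("refusing to write an FCS file with zero events")
    if not parameters:
        raise ValueError("no parameters selected")
    for col in parameters:
        if col not in events.columns:
            raise KeyError(f"column {col!r} not in event table")
        if not pd.api.types.is_numeric_dtype(events[col]):
            raise TypeError(f"column {col!r} is not numeric")

    data = np.ascontiguousarray(
        events[parameters].to_numpy(dtype="<f4", na_value=0.0)
    )
    n_events, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "{begindata}",
        "$ENDDATA": "{enddata}",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    finite_max = np.nanmax(np.abs(data)) if data.size else 0.0
    for i, name in enumerate(parameters, start=1):
        keywords[f"$P{i}N"] = str(name).replace(_DELIM, "_")
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, np.ceil(finite_max + 1))))
    if spillover is not None:
        names = spillover.channel_names
        vals = ",".join(
            [str(len(names))] + list(names)
            + [repr(float(v)) for v in np.asarray(spillover.coefficients).ravel()]
        )
        keywords["$SPILLOVER"] = vals.replace(_DELIM, "_")

    header_len = 58  # "FCS3.1" + 4 spaces + 6 × 8-byte offsets
    # two passes: offsets change the TEXT length, so reserve fixed width
    for _ in range(2):
        text_probe = _fcs_text(
            {k: v.format(begindata="0" * 10, enddata="0" * 10)
             if "{" in v else v for k, v in keywords.items()}
        )
        begin_text = header_len
        end_text = begin_text + len(text_probe) - 1
        begin_data = end_text + 1
        end_data = begin_data + data.nbytes - 1
    text = _fcs_text(
        {k: v.format(begindata=str(begin_data).rjust(10, "0"),
                     enddata=str(end_data).rjust(10, "0"))
         if "{" in v else v for k, v in keywords.items()}
    )
    assert len(text) == len(text_probe)

    def _hdr_offset(value: int) -> bytes:
        s = str(value) if value <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    "
    header += _hdr_offset(begin_text) + _hdr_offset(end_text)
    header += _hdr_offset(begin_data) + _hdr_offset(end_data)
    header += _hdr_offset(0) + _hdr_offset(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Minimal FCS reader (list mode, $DATATYPE F) for our own files."""
    raw = Path(path).read_bytes()
    if not raw[:6] == b"FCS3.1" and not raw[:6] == b"FCS3.0":
        raise ValueError(f"{path}: not an FCS 3.x file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text:end_text + 1].decode("ascii")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    kw = {tokens[i]: tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}
    begin_data = int(raw[26:34]) or int(kw["$BEGINDATA"])
    end_data = int(raw[34:42]) or int(kw["$ENDDATA"])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if kw.get("$DATATYPE") != "F":
        raise ValueError("only $DATATYPE F supported")
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    data = np.frombuffer(
        raw[begin_data:end_data + 1], dtype=f"{order}f4"
    ).reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(data.astype(np.float64), columns=names), kw


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks(tracks, path) -> None:
    """Write a TrackSet's spot table (plus frame interval) as CSV."""
    df = tracks.spots.copy()
    df.insert(0, "frame_interval_s", tracks.frame_interval_s)
    df.to_csv(path, index=False)


def read_tracks(path):
    """Read a spot/track CSV into a :class:`~hsbcyto.tracking.TrackSet`.

    Mandatory columns: ``time_index, track_id, x_um, y_um, z_um``; any
    further numeric columns (per-channel intensities, hue, ...) are carried
    along.  Rows are ordered by (track_id, time_index).
    """
    from .tracking import TrackSet

    df = pd.read_csv(path)
    missing = [c for c in TRACK_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: track table missing columns {missing}")
    frame_interval = None
    if "frame_interval_s" in df.columns:
        vals = df["frame_interval_s"].dropna().unique()
        if len(vals):
            frame_interval = float(vals[0])
        df = df.drop(columns=["frame_interval_s"])
    df = df.sort_values(["track_id", "time_index"], kind="stable")
    df = df.reset_index(drop=True)
    return TrackSet(spots=df, frame_interval_s=frame_interval)
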