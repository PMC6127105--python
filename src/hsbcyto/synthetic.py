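"""Synthetic fluorescence scenes and time-lapses with full ground truth.

Emulates the benchmark preparations the workflow was developed on: mixtures
of cells each carrying an arbitrary combination of up to three markers
(think DAPI / CFSE / propidium-iodide splenocyte mixes), imaged in three
spectral channels with additive spillover and Poisson-Gaussian noise.

Cells are ellipsoids placed without overlap by rejection sampling.  For a
cell with k ≥ 2 markers, each marker stains a half-space "cap" covering a
configurable fraction of the cell, with the caps oriented apart — the
partial-colocalization regime in which per-channel surface creation yields
incomplete objects while the brightness channel still captures the whole
cell.  Any cell voxel missed by every cap is assigned to the nearest cap,
so the union of marker supports always covers the cell.  Single-marker
cells are fully stained.

Time-lapses animate two or more classes of cells as fixed-speed persistent
random walks (steps re-aimed away from the border so the step length, and
hence the ground-truth speed, is preserved), with per-step speed jitter so
each class has realistic within-class dispersion.

Everything is driven by one integer seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compensation import SpilloverMatrix
from .hsb import hsb_from_arrays
from .image import MultiChannelImage, dtype_for_bit_depth
from .tracking import TrackSet

__all__ = [
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "TrackClassSpec",
    "generate_scene",
    "generate_timelapse",
]

MARKERS = ("R", "G", "B")

GENERATOR_ALGORITHM = "numpy-PCG64"  # rng recorded for reproducibility


def _normalize_combo(combo) -> frozenset:
    c = frozenset(str(m).upper() for m in combo)
    if not c or not c <= set(MARKERS):
        raise ValueError(f"marker combination must be a non-empty subset "
                         f"of {MARKERS}, got {combo!r}")
    return c


@dataclass
class SceneSpec:
    """Parameters of one synthetic static scene.

    ``n_cells`` maps a marker combination (e.g. ``"RG"``) to how many cells
    carry it.  ``coverage_fraction`` is the per-marker stained fraction of a
    multi-marker cell (1.0 = complete colocalization).  Intensities are
    per-cell Normal draws on the 8-bit-equivalent scale; noise is shot
    (Poisson, via ``poisson_gain`` photons per intensity unit) plus Gaussian
    read noise.  ``seed`` is mandatory — scenes are reproducible artifacts.
    """

    shape_zyx: tuple[int, int, int] = (24, 160, 160)
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 2.0)
    n_cells: dict = field(default_factory=lambda: {"R": 4, "G": 4, "B": 4})
    radius_um: tuple[float, float] = (3.0, 5.0)
    coverage_fraction: float = 1.0
    intensity_mean: float = 180.0
    intensity_sd: float = 20.0
    background: float = 0.0
    poisson_gain: float = 0.0   # 0 disables shot noise
    gaussian_sd: float = 0.0
    spillover: SpilloverMatrix | np.ndarray | None = None
    bit_depth: int = 8
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_cells = {_normalize_combo(k): int(v)
                        for k, v in self.n_cells.items()}
        if any(v < 0 for v in self.n_cells.values()):
            raise ValueError("cell counts must be >= 0")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class CellTruth:
    cell_id: int
    centre_um: np.ndarray          # (x, y, z)
    radii_um: np.ndarray           # (x, y, z)
    combination: frozenset
    voxels: np.ndarray             # (n, 3) int (z, y, x) — whole cell
    marker_support: dict           # marker -> (n, 3) int (z, y, x)
    true_intensity: dict           # marker -> float


@dataclass
class GroundTruth:
    cells: list
    labels: np.ndarray             # (Z, Y, X) int, cell_id per voxel
    spillover: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def combination_of(self, cell_id: int) -> frozenset:
        return self.cells[cell_id - 1].combination


def _spillover_array(spillover, c: int) -> np.ndarray:
    if spillover is None:
        return np.eye(c)
    if isinstance(spillover, SpilloverMatrix):
        return np.asarray(spillover.coefficients, dtype=np.float64)
    s = np.asarray(spillover, dtype=np.float64)
    if s.shape != (c, c):
        raise ValueError(f"spillover must be {c}×{c}")
    return s


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipsoid centres and radii."""
    vx, vy, vz = spec.voxel_size_um
    nz, ny, nx = spec.shape_zyx
    extent = np.array([nx * vx, ny * vy, nz * vz])
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    wanted = [(combo, None) for combo, n in sorted(
        spec.n_cells.items(), key=lambda kv: "".join(sorted(kv[0]))
    ) for _ in range(n)]
    out = []
    for combo, _ in wanted:
        r_iso = rng.uniform(*spec.radius_um)
        # mild anisotropy, z flattened toward the slice spacing regime
        radii = np.array([
            r_iso * rng.uniform(0.9, 1.1),
            r_iso * rng.uniform(0.9, 1.1),
            r_iso * rng.uniform(0.8, 1.0),
        ])
        for _attempt in range(2000):
            centre = np.array([
                rng.uniform(radii[0], extent[0] - radii[0]),
                rng.uniform(radii[1], extent[1] - radii[1]),
                rng.uniform(radii[2], extent[2] - radii[2]),
            ])
            if spec.allow_touching or all(
                np.linalg.norm(centre - c0) > radii.max() + r0.max() + 1.0
                for c0, r0 in placed
            ):
                placed.append((centre, radii))
                out.append((combo, centre, radii))
                break
        else:
            raise RuntimeError(
                f"could not place {len(wanted)} cells in "
                f"{extent.round(1)} µm; reduce counts or radii"
            )
    return out


def _ellipsoid_voxels(centre_um, radii_um, spec: SceneSpec) -> np.ndarray:
    vx, vy, vz = spec.voxel_size_um
    nz, ny, nx = spec.shape_zyx
    cx, cy, cz = centre_um
    rx, ry, rz = radii_um
    z0 = max(int((cz - rz) / vz) - 1, 0)
    z1 = min(int((cz + rz) / vz) + 2, nz)
    y0 = max(int((cy - ry) / vy) - 1, 0)
    y1 = min(int((cy + ry) / vy) + 2, ny)
    x0 = max(int((cx - rx) / vx) - 1, 0)
    x1 = min(int((cx + rx) / vx) + 2, nx)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    # voxel centres in µm
    pz = (zz + 0.5) * vz
    py = (yy + 0.5) * vy
    px = (xx + 0.5) * vx
    inside = (((px - cx) / rx) ** 2 + ((py - cy) / ry) ** 2
              + ((pz - cz) / rz) ** 2) <= 1.0
    return np.stack([zz[inside], yy[inside], xx[inside]], axis=1)


def _marker_caps(voxels: np.ndarray, centre_um, combo: frozenset,
                 coverage: float, spec: SceneSpec,
                 rng: np.random.Generator) -> dict:
    """Partition/cover the cell's voxels with one cap per marker.

    Each marker's support is the ``coverage`` quantile cap of a direction;
    directions are a common random rotation of k maximally spread unit
    vectors.  Voxels missed by all caps go to the cap with the largest
    margin, guaranteeing the union covers the cell.
    """
    markers = sorted(combo)
    k = len(markers)
    if k == 1 or coverage >= 1.0:
        return {m: voxels for m in markers}
    vx, vy, vz = spec.voxel_size_um
    pos = np.stack([
        (voxels[:, 2] + 0.5) * vx - centre_um[0],
        (voxels[:, 1] + 0.5) * vy - centre_um[1],
        (voxels[:, 0] + 0.5) * vz - centre_um[2],
    ], axis=1)
    if k == 2:
        base = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    else:
        ang = 2 * np.pi * np.arange(k) / k
        base = np.stack([np.cos(ang), np.sin(ang), np.zeros(k)], axis=1)
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    dirs = base @ q.T

    margins = np.empty((len(voxels), k))
    support = {}
    for j, (m, d) in enumerate(zip(markers, dirs)):
        proj = pos @ d
        thr = np.quantile(proj, 1.0 - coverage)
        margins[:, j] = proj - thr
        support[m] = voxels[proj >= thr]
    uncovered = (margins < 0).all(axis=1)
    if uncovered.any():
        best = margins[uncovered].argmax(axis=1)
        for j, m in enumerate(markers):
            extra = voxels[uncovered][best == j]
            if len(extra):
                support[m] = np.concatenate([support[m], extra])
    return support


def _render(spec: SceneSpec, cells: list, rng: np.random.Generator,
            S: np.ndarray) -> np.ndarray:
    nz, ny, nx = spec.shape_zyx
    true = np.zeros((3, nz, ny, nx), dtype=np.float64)
    for cell in cells:
        for m, vox in cell.marker_support.items():
            ci = MARKERS.index(m)
            true[ci, vox[:, 0], vox[:, 1], vox[:, 2]] = cell.true_intensity[m]
    observed = np.einsum("ij,izyx->jzyx", S, true)
    observed += spec.background
    if spec.poisson_gain > 0:
        observed = rng.poisson(observed / spec.poisson_gain) * spec.poisson_gain
    if spec.gaussian_sd > 0:
        observed = observed + rng.normal(0, spec.gaussian_sd, observed.shape)
    vmax = (1 << spec.bit_depth) - 1
    observed = np.clip(np.floor(observed + 0.5), 0, vmax)
    return observed.astype(dtype_for_bit_depth(spec.bit_depth))


def generate_scene(spec: SceneSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a static 3-channel scene and its complete ground truth."""
    rng = np.random.default_rng(spec.seed)
    S = _spillover_array(spec.spillover, 3)
    placements = _place_cells(spec, rng)
    nz, ny, nx = spec.shape_zyx
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    cells: list[CellTruth] = []
    for cid, (combo, centre, radii) in enumerate(placements, start=1):
        vox = _ellipsoid_voxels(centre, radii, spec)
        if len(vox) == 0:
            continue
        support = _marker_caps(vox, centre, combo, spec.coverage_fraction,
                               spec, rng)
        intensity = {
            m: max(float(rng.normal(spec.intensity_mean, spec.intensity_sd)),
                   1.0)
            for m in sorted(combo)
        }
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = cid
        cells.append(CellTruth(
            cell_id=cid, centre_um=np.asarray(centre),
            radii_um=np.asarray(radii), combination=combo, voxels=vox,
            marker_support=support, true_intensity=intensity,
        ))
    data = _render(spec, cells, rng, S)
    img = MultiChannelImage(
        data=data[np.newaxis].transpose(0, 2, 1, 3, 4),
        voxel_size_um=spec.voxel_size_um,
        channel_names=list(MARKERS),
        bit_depth=spec.bit_depth,
    )
    truth = GroundTruth(cells=cells, labels=labels, spillover=S)
    return img, truth


# ---------------------------------------------------------------------------
# time-lapse
# ---------------------------------------------------------------------------

@dataclass
class TrackClassSpec:
    """One motile population: marker combination, speed, count."""

    name: str
    combination: frozenset | str
    speed_um_s: float
    n_tracks: int
    speed_cv: float = 0.1      # per-step speed jitter (fraction of speed)
    persistence: float = 0.7   # directional memory per step, in [0, 1)

    def __post_init__(self) -> None:
        self.combination = _normalize_combo(self.combination)
        if self.speed_um_s < 0:
            raise ValueError("speed must be >= 0")


def generate_timelapse(
    classes: list,
    n_frames: int = 40,
    frame_interval_s: float = 30.0,
    shape_zyx: tuple[int, int, int] = (12, 200, 200),
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 4.0),
    cell_radius_um: float = 4.0,
    intensity_mean: float = 180.0,
    intensity_sd: float = 20.0,
    gaussian_sd: float = 0.0,
    spillover=None,
    bit_depth: int = 8,
    seed: int = 0,
    render: bool = True,
) -> tuple[MultiChannelImage | None, TrackSet]:
    """Animate ≥2 cell classes as persistent random walks.

    Returns the rendered 4D image (or ``None`` with ``render=False``) and
    the ground-truth :class:`TrackSet`: one spot per cell per frame with
    position, per-channel observed intensities (class intensities through
    spillover plus noise) and their HSB conversion.  The spot table carries
    a ``true_class`` column.

    Step length is exactly ``speed × Δt`` (modulated by the per-step jitter)
    — when a step would leave the volume its direction is resampled, never
    its length, so recorded positions reproduce the commanded speed.
    """
    if len(classes) < 2:
        raise ValueError("at least 2 track classes required")
    rng = np.random.default_rng(seed)
    vx, vy, vz = voxel_size_um
    nz, ny, nx = shape_zyx
    extent = np.array([nx * vx, ny * vy, nz * vz])
    margin = cell_radius_um
    for cls in classes:
        step = cls.speed_um_s * frame_interval_s
        if step >= extent.min() - 2 * margin:
            raise ValueError(
                f"class {cls.name!r}: step {step:.1f} µm exceeds the usable "
                f"extent {extent.min():.1f} µm; enlarge the volume or slow "
                "the cells"
            )
    S = _spillover_array(spillover, 3)

    rows = []
    tid = 0
    for cls in classes:
        for _ in range(cls.n_tracks):
            pos = np.array([
                rng.uniform(margin, extent[0] - margin),
                rng.uniform(margin, extent[1] - margin),
                rng.uniform(margin, extent[2] - margin),
            ])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            true_int = np.zeros(3)
            for m in cls.combination:
                true_int[MARKERS.index(m)] = max(
                    float(rng.normal(intensity_mean, intensity_sd)), 1.0
                )
            for t in range(n_frames):
                obs = S.T @ true_int
                if gaussian_sd > 0:
                    obs = obs + rng.normal(0, gaussian_sd, 3)
                vmaxv = (1 << bit_depth) - 1
                obs = np.clip(np.floor(obs + 0.5), 0, vmaxv)
                hue, sat, bri = hsb_from_arrays(obs[0], obs[1], obs[2])
                rows.append({
                    "track_id": tid, "time_index": t,
                    "x_um": pos[0], "y_um": pos[1], "z_um": pos[2],
                    "R": obs[0], "G": obs[1], "B": obs[2],
                    "hue": float(hue), "saturation_inv": float(sat),
                    "brightness": float(bri), "true_class": cls.name,
                })
                if t == n_frames - 1:
                    break
                speed = cls.speed_um_s * max(
                    1.0 + rng.normal(0, cls.speed_cv), 0.05
                )
                step_len = speed * frame_interval_s
                for _retry in range(200):
                    wobble = rng.normal(size=3)
                    wobble /= np.linalg.norm(wobble)
                    cand = cls.persistence * direction \
                        + (1 - cls.persistence) * wobble
                    norm = np.linalg.norm(cand)
                    if norm == 0:
                        continue
                    cand /= norm
                    new_pos = pos + cand * step_len
                    if ((new_pos > margin) & (new_pos < extent - margin)).all():
                        direction = cand
                        pos = new_pos
                        break
                else:
                    # aim back at the centre; keeps the step length exact
                    back = extent / 2 - pos
                    direction = back / np.linalg.norm(back)
                    pos = pos + direction * step_len
            tid += 1
    spots = pd.DataFrame(rows)
    tracks = TrackSet(spots=spots, frame_interval_s=frame_interval_s)

    img = None
    if render:
        vmax = (1 << bit_depth) - 1
        movie = np.zeros((n_frames, 3, nz, ny, nx), dtype=np.float64)
        for _, row in spots.iterrows():
            t = int(row["time_index"])
            centre = (row["x_um"], row["y_um"], row["z_um"])
            vox = _ellipsoid_voxels(
                centre, (cell_radius_um,) * 3,
                SceneSpec(shape_zyx=shape_zyx, voxel_size_um=voxel_size_um,
                          n_cells={}, seed=0),
            )
            if len(vox) == 0:
                continue
            for ci, ch in enumerate(("R", "G", "B")):
                np.maximum.at(
                    movie[t, ci], (vox[:, 0], vox[:, 1], vox[:, 2]),
                    row[ch],
                )
        data = np.clip(np.floor(movie + 0.5), 0, vmax)
        img = MultiChannelImage(
            data=data.transpose(0, 2, 1, 3, 4).astype(
                dtype_for_bit_depth(bit_depth)),
            voxel_size_um=voxel_size_um,
            channel_names=list(MARKERS),
            bit_depth=bit_depth,
            frame_interval_s=frame_interval_s,
        )
    return img, tracks
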