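# Methods

This note documents the models, conventions and numerical choices behind
`hsbcyto`, in the order data flows through the package.

## Image model and axes

All images are dense unsigned-integer arrays on a fixed axis order
(T, Z, C, Y, X), with singleton axes materialized, so a single plane and a
4D time-lapse flow through identical code. Coordinates are 0-based voxel
indices internally; physical micrometres appear only in exported statistics
(centroids, track positions). Bit depth (8, 12 or 16) is carried as
metadata — a 12-bit image lives in uint16 storage with intensities bounded
by 4095 — and is preserved across TIFF round trips via a JSON block in the
ImageJ `Info` tag, alongside channel names, voxel size and frame interval.
Written stacks are ordinary ImageJ hyperstacks readable by Fiji.

## Preprocessing

*Background removal* partitions the z axis into blocks of `z_chunk` slices
(default 10; the final block may be shorter and gets its own threshold) and
zeroes, per channel and block, every voxel below the block's threshold.
Thresholds are Otsu's method by default or a user-fixed intensity. One
convention worth noting: Otsu's split value conventionally belongs to the
background (foreground is v > t), whereas the zeroing rule is "strictly
below the threshold", so the working threshold is placed half an intensity
step above the Otsu value — on integer data the two conventions then agree.
Surviving voxels are bit-identical to the input; the operation never
increases a voxel.

*Log transform* maps v → round(log(1+v)/log(1+vmax) · vmax) per channel,
with vmax the channel scale. It is monotone and fixes both 0 and vmax, so
downstream integer arithmetic (including the HSB conversion) is unaffected
by the rescaling. The log1p form avoids a special case at zero; the output
normalisation back onto the channel scale is this package's choice.

*Mean filter* replaces each pixel by the mean over the in-plane Euclidean
disc of radius r pixels (13 pixels at the default r = 2.0), slice-wise,
with zero padding at borders. A 3D spherical footprint is available behind
the `three_d` flag but is not the default, because the in-plane pixel pitch
and the z step of typical two-photon stacks differ severalfold.

*Channel merging* is the voxelwise maximum of the selected channels — the
escape hatch when a panel has more than three markers, since the HSB
conversion takes exactly three inputs. Merging is associative, commutative
and idempotent; the merged channels' individual intensities remain
available per object at statistics extraction.

## The HSB transform

Per voxel with slot intensities (r, g, b), M = max, m = min:

- brightness B = M (the HSV "value"). A mean-based brightness was
  deliberately rejected: it would dim a single-positive cell threefold
  relative to a triple-positive one, undermining the single-pass surface
  property.
- inverted saturation S′ = round(m·(s_scale−1)/M), 0 when M = 0. This is
  1 − S_conventional rescaled, the minimal modification that makes white
  (triple-positive) maximal, pure colors minimal, and black zero with no
  further special casing.
- hue: the standard hexcone angle — 60°·((g−b)/Δ mod 6) when M = r,
  60°·((b−r)/Δ + 2) when M = g, 60°·((r−g)/Δ + 4) when M = b, with
  Δ = M − m — mapped onto the integer circle [0, hue_scale) (default 256)
  and rounded. Achromatic voxels (M = m) take hue 0 by convention.

Rounding is half-away-from-zero throughout (implemented as floor(x + 0.5);
all quantities are non-negative), so results are bit-reproducible. The
scaled saturation multiplies before dividing — m·(s_scale−1) is an exact
integer — so exact-half quotients (e.g. m = 1, M = 170 → 1.5) round
deterministically rather than at the mercy of accumulated float error.

Equal-intensity marker mixtures sit at fixed hues: R 0, RG 43, G 85,
GB 128, B 171, RB 213 on the 256 scale (0°, 60°, …, 300°). The full triple
is achromatic — hue carries no information about triple-positives, which is
why they are identified through S′ instead.

The hue LUT (`make_hue_lut`) renders entry h as the pure hue h at full
brightness: the maximal channel pinned at 255, the minimal at 0, the
intermediate channel quantized. With that construction the quantization
error in the recovered angle is at most 60°·0.5/255 ≈ 0.12°, below half a
hue step for any hue_scale ≤ 1530, so converting an entry back recovers its
index exactly — asserted exhaustively in tests.

## Surface creation and statistics

Segmentation from the brightness channel is a deliberately simple stand-in
for commercial surface-creation tools: threshold (Otsu or fixed), optional
splitting of touching cells by a watershed seeded at smoothed maxima of the
anisotropy-aware Euclidean distance transform (smoothing σ =
seed_diameter/4, seed spacing ≥ seed_diameter/2), connected components at
6/18/26-connectivity (default 26), removal of objects below `min_voxels`,
and dense relabelling 1..N. Splitting defaults on because cells in tissue
pack tightly. Empty foreground is a valid zero-object result.

Per-object statistics are volume (voxels), centroid (µm), and mean/median
per named channel — original, log-transformed and HSB channels alike. The
median of an even voxel count is the lower middle value: deterministic and
integer-preserving. The hue median is an ordinary median on the linear hue
scale, computed only over the object's voxels with brightness > 0 (unlit
voxels have no defined color); a hue straddling the red wrap-around is the
known limitation of the linear convention, and circular gates downstream
keep red-centred intervals expressible. `backgate` maps a gated id subset
back onto the label volume for spatial inspection.

## Spillover compensation

The mixing model is linear: observedⱼ = Σᵢ s[i,j]·trueᵢ with unit diagonal.
Coefficients are the least-squares slopes *through the origin* of
channel-j versus channel-i intensity over events (or pixels) of the
channel-i single-stain control — no intercept, because background is
removed upstream; a through-origin R² is recorded per coefficient.
Gated single-positive events are accepted in place of dedicated controls.
Compensation solves the C×C system per event or voxel, clamps negative
solutions to zero (flow-cytometry convention; raw signed values behind a
flag), and requantizes images to their bit depth. It operates on linear
intensities and must precede the log transform. Because gates act
row-wise, compensating-then-gating equals gating-then-compensating when
the gates are expressed in compensated space. Matrices round-trip through
a plain CSV with channel-name headers, so manual tweaking is a text edit.

## Gating and classification

Gates are named conjunctions of per-column inclusive intervals, optionally
hierarchical; an interval with lo > hi wraps through 0 (circular, for hue).
An event is assigned to the deepest gate whose full predicate chain it
satisfies; overlapping siblings resolve to the first listed — a manual
gating order made deterministic. The canonical 3-marker classification
assigns events with saturation_median ≥ threshold to the triple-positive
subset, and every other event to the single/double combination whose
expected hue is nearest on the circle within a tolerance (default
hue_scale/12, half the spacing between adjacent primary/secondary hues);
exact ties are ambiguous and left ungated. The saturation threshold is a
user decision applied after surfacing — changing it costs a re-gate, not a
re-segmentation.

## Tracking

Track statistics: median hue (same lower-median convention) and mean speed
= mean over consecutive spot pairs of 3D displacement divided by actual
elapsed time (gaps in time_index allowed); single-spot tracks have
undefined speed, recorded as missing. Hue filtering labels each track with
the first circular interval containing its median hue. Precision and
recall are counted per class over tracks; an empty denominator yields an
explicitly flagged undefined value, never a silent zero. Speed comparison
is the classical pooled-variance two-tailed unpaired Student's t test with
the 95% CI on the mean difference; Welch's variant is available behind a
flag. A greedy nearest-neighbour linker is bundled as plumbing for
end-to-end synthetic runs; tracking quality is not this package's
contribution.

## Synthetic data

The generator emulates the benchmark preparations the workflow targets:
mixtures of ellipsoidal cells carrying arbitrary combinations of three
markers, imaged with linear spillover and Poisson-Gaussian noise.

Static scenes: cells are placed by rejection sampling with no overlap
(bounded retries; failure suggests smaller counts). Radii default to
3–5 µm with mild anisotropy in a 0.5 × 0.5 × 2 µm voxel grid — a typical
confocal/two-photon regime. For a cell with k ≥ 2 markers, each marker
stains the cap of a direction (a common random rotation of k maximally
spread unit vectors) containing a configurable fraction of the cell's
voxels; voxels missed by every cap are assigned to the nearest cap, so the
union of marker supports always covers the cell — for single-marker cells
coverage is necessarily complete. Per-cell marker intensities are Normal
draws (default mean 180, SD 20 on the 8-bit scale); spillover is folded in
as observedⱼ = Σᵢ s[i,j]·trueᵢ; optional shot noise (Poisson with a
photons-per-unit gain) and Gaussian read noise are added before
quantization. Ground truth records every cell's centre, radii, combination,
per-marker support voxels and true intensities, plus a label volume.

Time-lapses: each class of cells performs a persistent random walk
(directional memory 0.7 per step) at its commanded speed with a small
per-step speed jitter (CV 0.1 — a zero-dispersion population would make
within-class standard errors degenerate and a t test ill-posed). When a
step would leave the volume its direction is resampled, never its length,
so recorded ground-truth positions reproduce the commanded speed exactly
up to the jitter. Default geometry (30 s frame interval, 4 µm z step)
mirrors typical intravital two-photon time-lapse settings. Spots carry the
class's observed (spillover-mixed, optionally noisy) intensities and their
HSB conversion.

Everything is driven by a single integer seed through one PCG64 generator;
identical parameters and seed give bit-identical output.

What the generator does **not** emulate: optical point-spread blurring,
photobleaching, autofluorescence, tissue texture, cell shape change, or
densely touching cell packing (unless `allow_touching`). Tests passing on
these scenes therefore validate the algebra and the pipeline logic — the
transform, surface completeness, compensation and classification — not
segmentation robustness on hard real data, where thresholds and seed
diameters must be tuned per dataset.

## Benchmark problem sizes

The shipped end-to-end checks use scenes of roughly 14 cells in
20 × 140 × 140 voxel volumes, single-stain controls of 6 cells per channel,
and time-lapses of 2 × 20 tracks over 40 frames — sizes chosen so the whole
suite runs in well under a minute while every statistic involved (slope
standard errors, class speed dispersions, per-object medians) remains
well-conditioned. The HSB transform is verified exhaustively over all 256³
8-bit triples against an independent hexcone implementation.

## File formats

TIFF: ImageJ hyperstack dialect for read and write; OME-TIFF and bare
stacks are read best-effort, with an explicit error (and an `axis_hint`
override) when the axis order is ambiguous. Tables: plain CSV, comma
separator, dot decimal, mandatory header. FCS: version 3.1, list mode,
little-endian single-precision floats, one parameter per selected numeric
column, with `$PAR`/`$TOT`/`$BEGINDATA`/`$ENDDATA` kept consistent; a
spillover matrix can be emitted as `$SPILLOVER`. A minimal FCS reader is
included for verification and re-import.
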