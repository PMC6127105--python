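# hsbcyto

Hue-saturation-brightness (HSB) surface creation for multi-channel
volumetric image cytometry.

## The problem

Quantifying cells in 3D fluorescence images ("histocytometry") requires
segmenting every cell into an object — a *surface* — and extracting its
per-channel statistics. When cells carry combinations of markers, the
traditional route builds one co-localization channel per marker combination
and masks already-surfaced signal out of the originals: for *n* markers that
is 2ⁿ − 1 channels (63 channels for a 6-marker panel), built sequentially
with no mistakes allowed, and any compensation or gating error forces a full
redo.

`hsbcyto` implements the alternative: assign up to three channels to the
red/green/blue slots of an RGB triple and convert each voxel with the
standard hexcone equations, with one deliberate modification. Writing
M = max(r, g, b) and m = min(r, g, b):

- **brightness** B = M — every voxel positive for *any* marker is captured,
  so a single segmentation pass over this one channel yields complete
  surfaces for all cells regardless of marker combination;
- **inverted saturation** S′ = m/M (0 when M = 0) — triple-positive (white)
  voxels score maximal, single- and double-positives score low, and pure
  black stays 0;
- **hue** H — the hexcone angle on an integer scale (default 0–255),
  identifying which one or two markers dominate, independent of brightness.

Cell subsets are then defined *after* surfacing, flow-cytometry style:
single/double-positives by gating hue, triple-positives by thresholding the
inverted saturation. Spectral spillover is likewise corrected after
surfacing, from slopes fit to single-stain controls, so fixing a
compensation error is a matrix edit instead of a re-segmentation. Object
statistics export to CSV and to FCS 3.1 for any flow-analysis tool, and
time-lapse tracks are classified by their median hue.

A fully ground-truthed synthetic generator (ellipsoidal cells with
configurable marker combinations, partial per-marker coverage, spillover,
Poisson-Gaussian noise, and motile populations for time-lapse) makes every
step testable without microscope data.

## Worked example

Fourteen synthetic cells, two per combination of three markers, surfaced
from the brightness channel alone and classified by hue + saturation:

```python
from hsbcyto import (SceneSpec, generate_scene, rgb_to_hsb, create_surfaces,
                     SegmentationParams, extract_statistics,
                     classify_by_hue_saturation, traditional_channel_count)

spec = SceneSpec(
    shape_zyx=(20, 140, 140),
    n_cells={"R": 2, "G": 2, "B": 2, "RG": 2, "GB": 2, "RB": 2, "RGB": 2},
    intensity_sd=10.0,
    seed=71,
)
img, truth = generate_scene(spec)
print("channels needed traditionally for 3 markers:",
      traditional_channel_count(3))

hsb = rgb_to_hsb(img)                      # hue / inverted sat / brightness
surf = create_surfaces(
    hsb.brightness[0],
    SegmentationParams(threshold=1, min_voxels=5, split_touching=False),
    voxel_size_um=img.voxel_size_um,
)
print("cells generated:", truth.n_cells, "| surfaces found:", surf.n_objects)

stats = extract_statistics(surf, {}, hsb=hsb)
subsets = classify_by_hue_saturation(stats, ("R", "G", "B"),
                                     sat_threshold=102.0)
print(subsets.counts().to_string())
```

prints

```
channels needed traditionally for 3 markers: 7
cells generated: 14 | surfaces found: 14
subset
R+B+      2
R+        2
R+G+B+    2
G+B+      2
R+G+      2
G+        2
B+        2
```

One pass over the brightness channel found all 14 cells (the traditional
route would have needed 7 derived channels and 7 segmentation passes), and
the hue/saturation gate recovered every generated marker combination. A
double-positive R+B cell, for instance, carries `hue_median ≈ 213`
(magenta, 300°) and `saturation_median 0`; a triple-positive carries
`saturation_median` near 255 and its hue is ignored.

The same pipeline is scriptable from the shell:

```sh
hsbcyto simulate --spec scene.yaml --out scene.tif --truth truth.csv
hsbcyto convert scene.tif --out hsb.tif
hsbcyto surface hsb.tif --channel brightness --threshold 1 \
        --no-split --stats-out stats.csv
hsbcyto export-fcs stats.csv --out events.fcs
hsbcyto lut --out hue.lut            # ImageJ LUT for native-hue rendering
```

See `docs/methods.md` for the model, parameter and numerical details.

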