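# tiptrace

Quantification of tip-growth dynamics of elongating cells (root hairs,
rhizoids, zygotes, pollen-tube-like cells) from 2-D time-lapse microscopy.

The pipeline:

1. **Segmentation** — global Otsu thresholding (`bright_object` /
   `dark_object` polarity), or ingestion of externally generated binary
   masks (e.g. from a promptable deep-learning segmenter). One cell per
   frame; largest component kept, holes filled.
2. **Contour** — subpixel closed boundary at iso-level 0.5, uniformly
   resampled, counterclockwise; optional lowess smoothing.
3. **Centerline** — Voronoi tessellation of the contour point cloud;
   interior vertices form the skeleton; clearance filtering and short-leaf
   pruning yield the main axis ("a centerline that does not reach the
   contour"); tip and bottom are found by fitting a total-least-squares line
   through the terminal skeleton points and intersecting the outward ray
   with the contour.
4. **Coordinate normalization** (optional) — rigid alignment of each frame
   to a reference by maximizing the normalized correlation
   `gamma(u, v, theta)` over translation + rotation (grid search with
   bisection refinement, zero fill outside the image). Skip with
   `--no-normalize` when the cell base is fixed experimentally.
5. **Kinematics** — cell length `L` (centerline arc length, um), tip
   velocity `dL/dt` (forward difference), velocity direction `delta-theta`
   (signed angle of the tip displacement vs. a reference axis;
   counterclockwise positive on a screen-up display).
6. **Signal profiling** — intensity profiles of a second channel sampled
   along centerline normals, arc-length kymographs (bottom- or
   tip-anchored, missing cells are NaN), and truncated-Gaussian band
   fitting (baseline + Gaussian, least squares restricted to a window) with
   band ends reported at `mu +/- k*sigma`.

A fully parameterized synthetic-movie generator (`tiptrace.synth`) renders
growing capsule cells with exact ground truth (tip/bottom/centerline/length,
applied jitter, band position) so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic movie with ground truth
tiptrace simulate --out sim/ --n-frames 10 --growth-rate 1.0 \
    --band-center-rel 0.6 --seed 7

# full pipeline (bottom anchor taken from the ground-truth table here)
tiptrace run sim/contour_channel.tif --signal sim/signal_channel.tif \
    --pixel-size 0.5 --dt 1.0 --bottom 63.5,105.1 --out out/

# with coordinate normalization and external masks
tiptrace run movie.tif --masks masks.tif --normalize --reference-frame 0 \
    --pixel-size 0.21 --dt 5 --bottom 120,400 --out out/

# kymograph + band fits from existing centerlines
tiptrace kymo sim/signal_channel.tif out/centerlines.csv \
    --pixel-size 0.5 --halfwidth 1.2 --out kymo/
```

Outputs per run: `contours.csv`, `centerlines.csv`, `tips.csv`,
`trace.csv` (time, tip/bottom, `L_um`, `dLdt`, `delta_theta_deg`),
`transforms.csv` (when normalizing), `kymograph.csv` / `.tif`, `bands.csv`,
plots, and `runlog.json` stamped with the config hash and package version.
Identical config + seed produces byte-identical tables.

## Python API

```python
from tiptrace import (SyntheticCellSpec, make_growing_cell, binarize_otsu,
                      extract_contour, contour_to_centerline)

spec = SyntheticCellSpec(n_frames=8, growth_rate=1.0, seed=7)
seq, truth = make_growing_cell(spec)
mask = binarize_otsu(seq.frames[0])
contour = extract_contour(mask)
cl = contour_to_centerline(contour, pixel_size=spec.pixel_size,
                           anchor=tuple(truth.bottoms[0]))
print(cl.length_um, cl.tip_point)
```

## Tests and acceptance

```sh
python -m pytest -q tests/                       # full suite
python -m pytest -q tests/test_acceptance.py     # acceptance criteria only
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` checks, on seeded synthetic fixtures: tip
localization within 1.5 px and length within max(2 px, 2%); rigid-transform
recovery with median error below (0.5 px, 0.5 px, 0.5 deg); growth-rate
recovery within 10% plus exact telescoping and rotation-equivariance
identities; Gaussian band-fit recovery (1% noise-free, sub-bin under
noise); kymograph consistency; agreement between the Voronoi centerline and
a distance-transform medial-axis oracle (< 1 px mean); and byte-level
determinism. `scripts/acceptance.py` runs an end-to-end self-check; there
are no numeric targets reproducible offline (the real-microscopy velocity
benchmarks require the external raw-data deposit), so it writes an empty
target map.

## Conventions

- Coordinates: `x` = column, `y` = row, origin at the top-left pixel
  centre, 0-based. Geometry is computed in pixels; micrometres appear only
  at reporting boundaries via `pixel_size`.
- Frames are 0-indexed; the time axis is `frame_index * dt`.
- `delta_theta` is computed after flipping y to mathematical orientation,
  so positive means counterclockwise on a screen-up display.

## Limitations

- One cell, one tip per movie (no multi-tip quantification).
- Rigid normalization only (growth is signal, not nuisance).
- Single-component band fits; no spot tracking.
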