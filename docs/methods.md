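# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `cecseg`. It states nothing empirically that the
test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The corneal endothelium is a postmitotic monolayer; its cell density
(cells/mm²) is the standard clinical measure of endothelial reserve.
Non-contact specular microscopy produces small grayscale frames (typically
260×476 px here) whose quality varies widely — tear-film artifacts,
over/under-exposure, guttae, and stromal edema can hide cell borders in
part or all of the frame. A clinically usable automated reader must both
estimate density where cells are visible and *abstain* (flag the image or
region as ungradable) where they are not.

## Pipeline

### Preprocessing

Every image (training and inference) passes through the same chain:

1. **Gaussian blur**, σ = 2 px. The nominal "radius 1" is advisory; the
   kernel half-width is `max(radius, ceil(3σ))` so the kernel actually
   supports the requested σ (a 3×3 kernel with σ = 2 would be a near-box
   filter). Reflective boundary handling avoids dark rims at the frame.
2. **White top-hat** with a disc of radius 15 px: image minus its
   grayscale opening. The disc exceeds one typical cell diameter
   (≈ 21 px spacing at 2500 cells/mm², 1 µm/px), so the cell mosaic passes
   through while illumination gradients at larger scales are flattened.
   The *white* variant is used because cells are bright on dark borders.
3. **Global histogram equalization** (256 bins). A constant image is
   returned unchanged (degenerate CDF). No locality (CLAHE) is used.

Each stage preserves dimensions and maps [0,1] into [0,1].

### Label synthesis from centroid dots

Ground truth is one dot per cell. Dense two-class label maps are
synthesized by marker-controlled watershed of the preprocessed image,
inverted so bright cell interiors are basins and the dark borders the
ridges; one marker per dot. The flooding (see *Watershed* below) produces
one-pixel lines that separate distinct basins with basin count equal to
marker count.

**Label line width.** The watershed line itself is 1 px, but the rendered
(and physical) border band is ~2 px; which of the band's pixels carries the
line is arbitrary at the pixel level. Training against a 1-px target makes
the network split its softmax mass across the band, and the fixed 60%
threshold then dissects the predicted lattice: cells merge, the median
Voronoi area inflates, and density is biased low by tens of percent (we
measured −54%/−67% on two held-out mosaics). Thickening the label line to
2 px (the default, `line_width=2`) makes the border class coincide with
the band and removes the bias (−3.6%/−7.2% on the same mosaics at the same
small training scale). Images with fewer than two dots yield an all-zero
label map plus a warning.

Patching follows the training-data arithmetic exactly: non-overlapping
78×78 tiles anchored at (0,0), partial right/bottom tiles discarded (a
260×476 frame gives 3·6 = 18 tiles), and four-way mirror augmentation
(identity, horizontal, vertical, both). 158 full-size frames therefore
yield 158·18·4 = 11,376 training patches.

### U-Net

A standard encoder/decoder with skip connections: `depth` levels
(default 3), `root_features`·2^level channels (default 26 root features),
two 3×3 convolutions + ReLU per level, 2×2 max pooling, 2×2 transposed
convolutions up, a 1×1 convolution onto two classes, softmax per pixel.
Implementation details:

* **NumPy implementation.** Forward and backward passes are written
  explicitly (im2col-style convolutions via sliding windows, argmax-cached
  pooling), with Adam (lr 1e-3 default, β = 0.9/0.999). A finite-difference
  gradient check is part of development history; the shipped tests verify
  training behavior (order-of-magnitude loss reduction when overfitting,
  background collapse on all-background labels, label reconstruction after
  single-patch overfitting).
* **"Same" convolutions** so the probability map matches the input raster;
  inputs are symmetric-padded up to a multiple of 2^(depth−1) and the
  logits cropped back. The original valid-convolution/overlap-tile scheme
  is deliberately not used: frames are predicted whole.
* **Schedule.** "Iterations" and "epochs" are two config fields:
  `epochs` passes of `iterations_per_epoch` optimizer steps (defaults
  150 × 200), batch size 16, seeded shuffling. Loss history and pixel
  accuracy are recorded per epoch.
* **Loss** is unweighted two-class pixel cross-entropy. No dropout or
  batch normalization.
* **Determinism.** Parameter init and batch order derive from the seed;
  prediction is deterministic for a fixed model.

### Post-processing and the ungradable rule

1. Threshold the border probability at 0.60.
2. Remove 8-connected border objects smaller than 1000 px. This is the
   step that eliminates noisy, low-visibility regions — and deliberately
   sacrifices recall for precision, as only the contiguous central mosaic
   survives.
3. Cell regions are 4-connected components of the complement (the 8/4
   duality prevents diagonal leaks). A component is kept only if it does
   not touch the frame and at least 50% of its boundary pixels are
   adjacent to retained border pixels; the frame-touching open surround is
   exactly the removed poor-quality area. There is no canonical rule for
   delimiting cells where the retained lattice is open at the frame; this
   frame rule is this package's choice.
4. One centroid per region: the maximum of the Euclidean distance map of
   the non-border class, restricted to the region. A maximal plateau
   yields its center of mass snapped to the nearest plateau pixel (ties:
   smallest (y, x)). Regions whose distance peak is below
   `min_peak_separation` (default 2 px) — hairline holes in the lattice —
   yield no centroid.
5. `gradable` is true iff at least one centroid was extracted; an image
   with none is reported ungradable instead of receiving a density.

### Watershed

One implementation serves label synthesis and the baseline: Meyer's
flooding with an explicit priority queue ordered by (relief value,
insertion order), markers seeded in raster order, 8-connected flooding.
A pixel whose resolved neighbors span ≥ 2 basins becomes a one-pixel
watershed-line pixel; line pixels also carry the smallest adjacent basin
label so the label raster partitions the frame (needed by the baseline,
which assigns every pixel). The naive re-scan of the same definition is
kept in the test suite as a brute-force oracle, and agreement with
`skimage.segmentation.watershed` basin membership is cross-checked on
smooth reliefs. Tie-breaking is fully deterministic.

### Classical baseline

The historical marker-driven watershed chain:

1. **Alternating sequential filter**: (opening then closing) with discs of
   radius 1 … `asf_max_radius` (default 2) in increasing order.
2. **h-dome / h-maxima markers.** The h-dome transform is
   `dome = f − Rec_f(f − h)` (grayscale reconstruction by dilation,
   default h = 0.1 on [0,1] intensities). Markers are the regional maxima
   of the *difference image* `f − dome = Rec_f(f − h)` — the h-maxima
   transform — i.e. peaks with prominence ≥ h. Maxima of the dome raster
   itself would make h inert: any noise bump of any prominence is its own
   dome maximum (we measured 2.6–11× over-detection on clean mosaics under
   that reading, at every h). A connected plateau counts as a maximum only
   if strictly above all its neighbors, so a constant image yields no
   markers; marker components below `min_marker_px` (default 3) are
   discarded. Note the degenerate dome of a constant image is a flat
   raster at the h cap, not zero — the reconstruction of a constant marker
   has nothing to climb back to.
3. **Watershed** of the inverted filtered image from those markers; every
   pixel is assigned, one region per marker, one centroid per region by
   the same distance-map convention as above.

No region-of-interest masking is applied. That absence is the point of the
comparison: in unreadable regions the baseline happily plants markers (or
spills regions) and reports cells, where the learned pipeline's
small-object removal abstains.

A scale caveat: the ASF structuring element must be narrower than the
border band, or the closing bridges the dark borders and destroys the
mosaic before markers are found. With 2-px borders even radius 1 (3-px
disc) is borderline; the baseline tests therefore use 3-px-border mosaics
with `asf_max_radius=1`, the regime where the classical method is
operable on clean regions.

### Density estimation

Voronoi tessellation of the centroid set, clipped to the frame. A centroid
is a *border centroid* — excluded — if its cell is unbounded or touches
the frame rectangle, since such areas are artifacts of the field of view.
Density is `1 / median(interior areas)` converted by
`(microns_per_pixel / 1000)²`; the median of an even count is the mean of
the central pair. Fewer than four points, or a degenerate (collinear)
configuration, flags everything border and the estimate is ungradable.
`microns_per_pixel` has no universally correct value (it is the
microscope's video-print pixel pitch); it is a required calibration, fixed
to 1.0 µm/px throughout the synthetic studies so ground-truth densities
are self-consistent.

### Evaluation

* **Centroid matching**: one-to-one, maximum cardinality among pairs
  within the 8-px tolerance radius, computed exactly via a linear
  assignment with a large penalty on out-of-tolerance pairs (ties broken
  by minimal total distance). A greedy nearest-first matcher is *not*
  maximum-cardinality (crossing configurations), hence the exact solver.
* **Recall** = matched/truth, **precision** = matched/predicted; an empty
  denominator yields NaN, and NaN per-image metrics are excluded from
  corpus means (recorded in the report metadata).
* **Density agreement**: squared Pearson correlation plus the fraction of
  images within ±250 and ±500 cells/mm².
* **Ungradable detection**: 2×2 expert-vs-automatic cross-tabulation.

## Synthetic data generator

The generator is the package's study bed: specular-microscopy-like mosaics
with exact ground truth.

* **Geometry.** Cell centers on a hexagonal lattice with spacing
  `s = sqrt(2 / (√3 · density)) / (mm/px)` — so the nominal density is
  analytic — jittered uniformly by ±`jitter`·s (default 0.15) to model
  pleomorphism. The lattice extends one cell beyond the frame so edge
  pixels belong to real cells.
* **Appearance.** Borders are dark bands (default width 2 px, darkness
  0.35) along the Voronoi edges of the point set; interiors are bright
  with per-cell variation (0.72 ± 0.08); a linear illumination gradient
  (span 0.15, random orientation), additive Gaussian sensor noise
  (σ = 0.03 — applied last, also inside degraded regions), clipping to
  [0,1].
* **Degradations.** Guttae are dark discs (radius 8–20 px) that occlude
  local borders; any cell they overlap is removed from the truth dotting,
  mirroring an expert's refusal to dot ambiguous cells. A contiguous
  blurred band covering `blur_region_fraction` of the frame (side chosen
  by seed or fixed) is smoothed beyond readability; its cells are removed
  from the truth and from the readable mask. `blur_region_fraction=1`
  produces a fully ungradable frame.
* **Ground truth.** Each sample carries the visible-cell centroids, the
  visible border raster, the readable mask, the blur mask, and the nominal
  density computed from the interior Voronoi areas of the generating point
  set (within 5% of the requested target at default jitter).
* **Corpora.** `generate_corpus` draws densities uniformly over a range
  (default 500–3000 cells/mm²; the end-to-end study uses 800–3000), makes
  `round(n · ungradable_fraction)` samples fully unreadable, gives a
  configurable fraction partial blur and guttae, and writes images,
  centroid CSVs, border maps, and a manifest in the package's standard
  formats, byte-reproducibly per seed.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: specular highlights, Descemet's folds
(curvilinear dark structures), spatially correlated noise, realistic
guttae texture, contrast loss that varies smoothly rather than by region,
and true rater error in dotting (truth dots are exact cell centers). Real
corpora also have far more heterogeneous cell shape statistics than a
jittered hexagonal lattice.

## Reduced-scale study conditions

Training at full defaults (26 root features, 150×200 steps) is a
several-hour CPU run; the shipped end-to-end study (test suite and
`scripts/acceptance.py`) uses the same pipeline at a scale this package
adopts as its verification condition: 40-image corpus (10% ungradable,
800–3000 cells/mm²), training on 30 gradable images with 8 root features,
12 epochs × 100 iterations, batch 8, and segmentation of the 10 held-out
frames. The network is identical in form; only capacity and step count are
reduced.

## Known limitations

* The U-Net is CPU-sized; no GPU path, no mixed precision. Full-default
  training is slow, and nothing here aims to reproduce any particular
  trained model's weights.
* Recall is structurally limited by design: the 1000-px small-object rule
  removes every cell outside the contiguous central mosaic. Density, not
  recall, is the target quantity.
* Pleomorphism/polymegethism (cell shape/size variability metrics) are out
  of scope.
* The classical baseline's parameters are scale-sensitive (see the ASF
  caveat above); its defaults are tuned to CEC-like imagery, not general
  microscopy.
* `microns_per_pixel` must be supplied by the user for real hardware;
  densities are only as correct as that calibration.
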