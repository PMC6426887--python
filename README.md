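# cecseg — corneal endothelial cell segmentation and density estimation

`cecseg` is a fully automated pipeline for estimating corneal endothelial
cell (CEC) density from non-contact specular microscopy images, aimed at
ophthalmic imaging groups and computer-vision researchers who need a
segmentation method that survives *real-world* image quality: variable
exposure, blurred regions, guttae, and frames with no visible cells at all.

CEC density (cells/mm²) is the key clinical parameter for monitoring
endothelial health; counting requires locating every cell, which experts do
by "dotting" one point per cell. `cecseg` automates this with a
centroid-supervised U-Net and includes the classical watershed pipeline as
a baseline, plus a synthetic mosaic generator so the whole system can be
trained and validated without any clinical data.

## Method

**Label synthesis from dots.** Expert annotations are sparse centroids, not
border drawings. Dense two-class label maps (cell border / not border) are
synthesized by marker-controlled watershed: each dot seeds a basin on the
preprocessed, inverted intensity relief, and the watershed lines between
basins become the border class.

**Preprocessing.** Gaussian blur (σ = 2 px) → grayscale white top-hat
(disc, radius 15 px) → histogram equalization, applied identically before
training and inference.

**Segmentation network.** A small U-Net (3 levels, 26 root features, 3×3
convolutions, 2×2 max pooling, two output classes) maps a preprocessed
frame to a per-pixel border probability map P(border | x). Training uses
78×78 patches, four-way mirror augmentation, and Adam on pixel-wise
cross-entropy. The network is implemented compactly in NumPy (explicit
forward/backward passes), so there is no deep-learning framework
dependency.

**Post-processing and the ungradable rule.** Probability maps are
thresholded at 60%; connected border objects under 1000 px are removed —
this is what strips regions of poor visibility, leaving only the contiguous
central mosaic. Cell centroids are the local maxima of the Euclidean
distance map of the non-border class, one per enclosed cell region. An
image yielding zero centroids is declared *ungradable* rather than
producing a fabricated density.

**Density.** Cell areas come from the Voronoi tessellation of the extracted
centroids; centroids whose Voronoi cell is unbounded or touches the frame
are excluded as border centroids, and

    density = 1 / median(interior Voronoi areas),

converted to cells/mm² by the microscope's pixel pitch (explicit
`microns_per_pixel` calibration).

**Baseline.** Vincent's classical chain — alternating sequential filter,
h-dome transform, regional maxima of the reconstruction as markers,
marker-controlled watershed — segments every frame whole, which is exactly
why it over-detects in unreadable regions.

**Evaluation.** Predicted centroids are matched one-to-one to expert dots
within an 8-px radius (exact maximum-cardinality assignment); recall,
precision, Pearson R² of density agreement, ±250/±500 cells/mm² agreement
corridors, and an ungradable-detection cross-tab are reported.

## Worked example

```python
import numpy as np
from cecseg import MosaicSpec, generate_sample, UNetBorderSegmenter, VincentSegmenter

# synthetic corpus: eight annotated mosaics across a density range
rng = np.random.default_rng(0)
train = [generate_sample(MosaicSpec(seed=100 + i, target_density=float(d)))
         for i, d in enumerate(rng.uniform(800, 3000, 8))]
test = generate_sample(MosaicSpec(seed=200, target_density=1400.0))

seg = UNetBorderSegmenter(root_features=8, epochs=10, iterations_per_epoch=60,
                          batch_size=8, random_state=0)
seg.fit([s.image for s in train], [s.truth_centroids for s in train])

result = seg.predict([test.image])[0]
density = seg.predict_density([test.image])[0]
print(f"gradable={result.gradable} cells={len(result.centroids)} "
      f"density={density.cells_per_mm2:.0f} truth={test.truth_density:.0f}")
```

Output from this exact script (a deliberately small training run,
~3 minutes on one CPU):

```
gradable=True cells=119 density=1355 truth=1407
```

119 of the mosaic's cells were extracted from the cleaned border network
and their median Voronoi area yields 1355 cells/mm² against a ground truth
of 1407 (−3.7%); longer training at the defaults tightens this further.

The same estimators expose the scikit-learn surface
(`get_params`/`set_params`, fitted attributes such as `model_`,
`history_`), and `VincentSegmenter` offers the identical `predict` /
`predict_density` API without training.

A command-line interface mirrors the library:

```bash
cecseg synth --n 40 --out corpus/
cecseg train --manifest corpus/manifest.csv --n-train 30 --out run/
cecseg segment --model run/model.npz --out run/seg 'corpus/synth_00*.png'
cecseg vincent --out run/vincent 'corpus/synth_00*.png'
cecseg evaluate --pred pred.csv --truth truth.csv --out run/eval
```

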