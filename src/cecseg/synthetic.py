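"""Synthetic specular-microscopy-like endothelial mosaics with exact ground truth.

Healthy endothelium is a near-hexagonal monolayer, so cell centers are laid
out on a jittered hexagonal lattice whose spacing realizes a requested
density exactly ((sqrt(3)/2) * s^2 per cell).  Rendering emulates the
features that drive real-image difficulty: bright polygonal interiors with
per-cell brightness variation separated by dark borders, a linear
illumination gradient, additive sensor noise, guttae as dark discs that
occlude local borders, and a contiguous blurred region in which no cells
are discernible.  Every sample carries its ground truth: visible-cell
centroids, visible-border map, nominal density, and a readability mask.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from . import io as cio
from .density import ScaleCalibration, estimate_density
from .labels import BorderLabelMap

__all__ = ["MosaicSpec", "SyntheticSample", "sample_cell_centers", "render_mosaic", "generate_sample", "generate_corpus"]

_SIDES = ("bottom", "top", "left", "right")


@dataclass(frozen=True)
class MosaicSpec:
    """Study conditions for one synthetic mosaic.

    Defaults mimic a mid-range specular video print: 260x476 frame,
    2500 cells/mm^2 at 1 um/px, moderate jitter (pleomorphism), 2-px dark
    borders, mild noise and illumination gradient, no guttae, no
    unreadable region.
    """

    width: int = 260
    height: int = 476
    target_density: float = 2500.0
    scale: ScaleCalibration = ScaleCalibration(1.0)
    jitter: float = 0.15
    border_width: float = 2.0
    border_darkness: float = 0.35
    noise_sigma: float = 0.03
    illumination_gradient: float = 0.15
    n_guttae: int = 0
    guttae_radius_range: tuple = (8.0, 20.0)
    blur_region_fraction: float = 0.0
    blur_region_side: str = "auto"  # "auto" draws a side from the seed
    seed: int = 0

    def __post_init__(self):
        if self.target_density <= 0:
            raise ValueError("target_density must be > 0")
        if not (0.0 <= self.jitter < 0.5):
            raise ValueError("jitter must be in [0, 0.5)")
        if not (0.0 <= self.blur_region_fraction <= 1.0):
            raise ValueError("blur_region_fraction must be in [0, 1]")
        if self.blur_region_side not in ("auto",) + _SIDES:
            raise ValueError(f"unknown blur_region_side {self.blur_region_side!r}")

    @property
    def lattice_spacing_px(self) -> float:
        """Spacing s with (sqrt(3)/2) s^2 (mm/px)^2 = 1/density."""
        mm_per_px = self.scale.microns_per_pixel / 1000.0
        return math.sqrt(2.0 / (math.sqrt(3.0) * self.target_density)) / mm_per_px


@dataclass(frozen=True)
class SyntheticSample:
    image: cio.GrayImage
    truth_centroids: cio.CentroidSet
    truth_borders: BorderLabelMap
    truth_density: float
    readable_mask: np.ndarray  # 1 where cells were rendered visible
    blur_mask: np.ndarray  # 1 inside the unreadable blurred region
    spec: MosaicSpec


def sample_cell_centers(spec: MosaicSpec) -> np.ndarray:
    """Jittered hexagonal lattice covering the frame plus a one-cell margin.

    The margin guarantees that frame-edge pixels belong to real cells, so
    border rendering is correct up to the frame.
    """
    s = spec.lattice_spacing_px
    if s < 3.0:
        raise ValueError(
            f"target_density {spec.target_density} gives lattice spacing {s:.2f} px < 3 px"
        )
    rng = np.random.default_rng(spec.seed)
    dy = s * math.sqrt(3.0) / 2.0
    margin = 2.0 * s
    rows = np.arange(-margin, spec.height + margin, dy)
    pts = []
    for i, y in enumerate(rows):
        x0 = -margin + (s / 2.0 if i % 2 else 0.0)
        xs = np.arange(x0, spec.width + margin, s)
        pts.extend((x, y) for x in xs)
    pts = np.asarray(pts, dtype=float)
    if spec.jitter > 0:
        pts = pts + rng.uniform(-spec.jitter * s, spec.jitter * s, size=pts.shape)
    return pts


def _blur_band(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    f = spec.blur_region_fraction
    if f <= 0:
        return mask
    side = spec.blur_region_side
    if side == "auto":
        side = _SIDES[rng.integers(len(_SIDES))]
    if side in ("top", "bottom"):
        k = int(round(f * spec.height))
        if side == "top":
            mask[:k, :] = True
        else:
            mask[spec.height - k :, :] = True
    else:
        k = int(round(f * spec.width))
        if side == "left":
            mask[:, :k] = True
        else:
            mask[:, spec.width - k :] = True
    return mask


def render_mosaic(points: np.ndarray, spec: MosaicSpec) -> SyntheticSample:
    """Rasterize the Voronoi mosaic of ``points`` with the spec's degradations."""
    h, w = spec.height, spec.width
    s = spec.lattice_spacing_px
    rng = np.random.default_rng(spec.seed + 1)

    yy, xx = np.mgrid[0:h, 0:w]
    _, lab = cKDTree(points).query(np.column_stack([xx.ravel(), yy.ravel()]))
    lab = lab.reshape(h, w)

    # border skeleton: pixels whose right or lower neighbor is another cell
    edge = np.zeros((h, w), dtype=bool)
    edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    edge[:-1, :] |= lab[:-1, :] != lab[1:, :]
    dist_to_edge = ndi.distance_transform_edt(~edge)
    border = dist_to_edge <= (spec.border_width - 1.0) / 2.0

    brightness = 0.72 + rng.uniform(-0.08, 0.08, size=len(points))
    img = brightness[lab]
    img = np.where(border, img - spec.border_darkness, img)

    if spec.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        ramp = (xx * math.cos(theta) + yy * math.sin(theta)).astype(float)
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1.0)
        img = img + spec.illumination_gradient * (ramp - 0.5)

    excluded = np.zeros(len(points), dtype=bool)
    readable = np.ones((h, w), dtype=bool)
    visible_border = border.copy()

    for _ in range(spec.n_guttae):
        r = rng.uniform(*spec.guttae_radius_range)
        cx = rng.uniform(0, w - 1)
        cy = rng.uniform(0, h - 1)
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img = np.where(disc, 0.12, img)
        visible_border &= ~disc
        readable &= ~disc
        excluded[np.unique(lab[disc])] = True

    blur = _blur_band(spec, rng)
    if blur.any():
        blurred = ndi.gaussian_filter(img, sigma=1.5 * s, mode="reflect")
        img = np.where(blur, blurred, img)
        visible_border &= ~blur
        readable &= ~blur
        excluded[np.unique(lab[blur])] = True

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    in_frame = (
        (points[:, 0] >= 0)
        & (points[:, 0] <= w - 1)
        & (points[:, 1] >= 0)
        & (points[:, 1] <= h - 1)
    )
    truth_idx = np.flatnonzero(in_frame & ~excluded)
    truth = cio.CentroidSet(image_id=f"synthetic-{spec.seed}", points=points[truth_idx])

    # nominal density of the generating point set, from its interior Voronoi areas
    all_pts = cio.CentroidSet(image_id="", points=points)
    est = estimate_density(all_pts, (w, h), spec.scale)
    truth_density = est.cells_per_mm2 if est.gradable else spec.target_density

    return SyntheticSample(
        image=cio.GrayImage(img, id=truth.image_id),
        truth_centroids=truth,
        truth_borders=BorderLabelMap(visible_border.astype(np.uint8), image_id=truth.image_id),
        truth_density=float(truth_density),
        readable_mask=readable.astype(np.uint8),
        blur_mask=blur.astype(np.uint8),
        spec=spec,
    )


def generate_sample(spec: MosaicSpec) -> SyntheticSample:
    """Convenience: sample centers and render in one call."""
    return render_mosaic(sample_cell_centers(spec), spec)


def generate_corpus(
    n: int,
    out_dir: str,
    seed: int,
    density_range: tuple = (500.0, 3000.0),
    ungradable_fraction: float = 0.1,
    degraded_fraction: float = 0.3,
    guttae_fraction: float = 0.2,
    base_spec: MosaicSpec = MosaicSpec(),
):
    """Write a synthetic corpus (images, centroid CSVs, border maps, manifest).

    Exactly ``round(n * ungradable_fraction)`` samples are fully unreadable
    (ungradable); a further ``degraded_fraction`` carry a partial blurred
    region, and ``guttae_fraction`` carry 1-3 guttae.  Densities are drawn
    uniformly over ``density_range``.  Deterministic per seed.

    Returns (CorpusManifest, list of SyntheticSample).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_ungradable = int(round(n * ungradable_fraction))
    records = []
    samples = []
    for i in range(n):
        density = float(rng.uniform(*density_range))
        ungradable = i < n_ungradable
        degraded = rng.random() < degraded_fraction
        n_guttae = int(rng.integers(1, 4)) if rng.random() < guttae_fraction else 0
        spec = replace(
            base_spec,
            target_density=density,
            n_guttae=0 if ungradable else n_guttae,
            blur_region_fraction=1.0 if ungradable else (float(rng.uniform(0.1, 0.4)) if degraded else 0.0),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sample = generate_sample(spec)
        image_id = f"synth_{i:04d}"
        sample = _rename(sample, image_id)
        samples.append(sample)
        cio.write_image(sample.image, os.path.join(out_dir, f"{image_id}.png"))
        cio.write_image(
            cio.GrayImage(sample.truth_borders.mask.astype(float), id=image_id),
            os.path.join(out_dir, f"{image_id}_borders.png"),
        )
        annotation_path = ""
        if not ungradable:
            annotation_path = f"{image_id}.csv"  # relative to the corpus dir
            cio.write_centroids(sample.truth_centroids, os.path.join(out_dir, annotation_path))
        records.append(
            cio.ManifestRecord(
                image_id=image_id,
                split="validation",
                ungradable=ungradable,
                guttae=spec.n_guttae > 0,
                annotation_path=annotation_path,
            )
        )
    manifest = cio.CorpusManifest(records)
    cio.write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest, samples


def _rename(sample: SyntheticSample, image_id: str) -> SyntheticSample:
    return SyntheticSample(
        image=cio.GrayImage(sample.image.pixels, id=image_id),
        truth_centroids=cio.CentroidSet(image_id=image_id, points=sample.truth_centroids.points),
        truth_borders=BorderLabelMap(sample.truth_borders.mask, image_id=image_id),
        truth_density=sample.truth_density,
        readable_mask=sample.readable_mask,
        blur_mask=sample.blur_mask,
        spec=sample.spec,
    )
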