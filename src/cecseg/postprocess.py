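"""From border-probability map to cleaned border network, centroids, and
the ungradable decision.

The probability map is thresholded (default 60%), connected border objects
smaller than 1000 pixels are removed — this is what strips noisy,
poor-quality image regions and keeps only the contiguous central mosaic —
and cell centroids are extracted as local maxima of the Euclidean distance
map of the non-border class, one per enclosed cell region.  An image whose
cleaned output yields no centroid is declared ungradable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import CentroidSet
from .labels import BorderLabelMap
from .unet import ProbabilityMap

__all__ = [
    "PostprocessParams",
    "SegmentationResult",
    "binarize",
    "remove_small_objects",
    "extract_centroids",
    "region_centroids",
]

_S4 = ndi.generate_binary_structure(2, 1)
_S8 = ndi.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class PostprocessParams:
    """prob_threshold and min_object_px follow the pipeline definition;
    min_peak_separation is the minimum distance-map peak (in px) a region
    must reach to yield a centroid, suppressing hairline holes in the
    border lattice."""

    prob_threshold: float = 0.60
    min_object_px: int = 1000
    min_peak_separation: float = 2.0

    def __post_init__(self):
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")


@dataclass(frozen=True)
class SegmentationResult:
    centroids: CentroidSet
    border_mask: BorderLabelMap
    cell_regions: np.ndarray  # int label per detected cell, 0 = unassigned
    gradable: bool

    def __post_init__(self):
        if self.gradable != (len(self.centroids) > 0):
            raise ValueError("gradable flag must equal (n centroids > 0)")


def binarize(pm: ProbabilityMap, params: PostprocessParams = PostprocessParams()) -> BorderLabelMap:
    """Border mask = 1 where probability >= threshold."""
    return BorderLabelMap(
        (pm.probs >= params.prob_threshold).astype(np.uint8), image_id=pm.image_id
    )


def remove_small_objects(
    mask: BorderLabelMap, params: PostprocessParams = PostprocessParams()
) -> BorderLabelMap:
    """Drop 8-connected foreground objects with fewer than min_object_px pixels."""
    lab, n = ndi.label(mask.mask, structure=_S8)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= params.min_object_px
    keep[0] = False
    return BorderLabelMap(keep[lab].astype(np.uint8), image_id=mask.image_id)


def _plateau_centroid(dist: np.ndarray, region: np.ndarray) -> tuple:
    """One deterministic centroid for a region: the maximal-distance plateau's
    center of mass, snapped to the nearest plateau pixel (ties: smallest (y, x))."""
    vals = dist[region]
    dmax = vals.max()
    plateau = region & (dist >= dmax - 1e-9)
    ys, xs = np.nonzero(plateau)
    cy, cx = ys.mean(), xs.mean()
    d2 = (ys - cy) ** 2 + (xs - cx) ** 2
    best = np.lexsort((xs, ys, d2))[0]
    return float(xs[best]), float(ys[best]), float(dmax)


def region_centroids(
    border: np.ndarray,
    regions: np.ndarray,
    n_regions: int,
    min_peak: float = 0.0,
):
    """Shared centroid convention: per labeled region, the distance-map
    (EDT to the nearest border pixel) maximum, plateau-resolved."""
    dist = ndi.distance_transform_edt(border == 0)
    points = []
    kept_labels = []
    for lbl in range(1, n_regions + 1):
        region = regions == lbl
        if not region.any():
            continue
        x, y, dmax = _plateau_centroid(dist, region)
        if dmax < min_peak:
            continue
        points.append((x, y))
        kept_labels.append(lbl)
    return points, kept_labels, dist


def extract_centroids(
    mask: BorderLabelMap, params: PostprocessParams = PostprocessParams()
) -> SegmentationResult:
    """Centroids via local maxima of the distance map of the cleaned mask.

    Cell regions are the 4-connected components of the non-border class
    that (a) do not touch the image frame and (b) have retained border
    pixels along at least half of their boundary — the frame-touching open
    surround left after small-object removal is exactly the poor-quality
    area the pipeline is meant to ignore.  One centroid per region.
    """
    border = mask.mask.astype(bool)
    comp, n = ndi.label(~border, structure=_S4)

    # frame-touching components
    frame_labels = set(np.unique(np.concatenate([
        comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]
    ])))
    frame_labels.discard(0)

    border_dil = ndi.binary_dilation(border, structure=_S8)
    keep = []
    for lbl in range(1, n + 1):
        if lbl in frame_labels:
            continue
        region = comp == lbl
        interior = ndi.binary_erosion(region, structure=_S8, border_value=0)
        boundary = region & ~interior
        nb = boundary.sum()
        if nb == 0:
            continue
        frac = border_dil[boundary].sum() / nb
        if frac >= 0.5:
            keep.append(lbl)

    regions = np.zeros_like(comp)
    for new, lbl in enumerate(keep, start=1):
        regions[comp == lbl] = new

    points, kept, _ = region_centroids(border, regions, len(keep), params.min_peak_separation)
    # regions whose peak was too shallow are dropped from the label raster too
    if len(kept) != len(keep):
        remap = np.zeros(len(keep) + 1, dtype=regions.dtype)
        for new, old in enumerate(kept, start=1):
            remap[old] = new
        regions = remap[regions]

    centroids = CentroidSet(image_id=mask.image_id, points=np.array(points, dtype=float).reshape(-1, 2))
    return SegmentationResult(
        centroids=centroids,
        border_mask=mask,
        cell_regions=regions,
        gradable=len(points) > 0,
    )
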