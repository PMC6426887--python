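"""Vincent's classical marker-driven watershed segmenter.

The historical comparison pipeline: an alternating sequential filter
(opening then closing with discs of increasing radius) suppresses noise,
the h-dome transform isolates bright cell-interior peaks, the regional
maxima of the dome image become markers, and a marker-constrained
watershed of the inverted filtered image partitions the frame into cells.
No region-of-interest masking is applied — the method segments the whole
frame, which is what makes it over-detect in poor-quality regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima, reconstruction

from .io import CentroidSet, GrayImage
from .labels import BorderLabelMap
from .postprocess import SegmentationResult, region_centroids
from .preprocess import disk_footprint
from .watershed import watershed

__all__ = ["VincentParams", "asf_filter", "hdome", "vincent_markers", "vincent_segment"]


@dataclass(frozen=True)
class VincentParams:
    asf_max_radius: int = 2
    hdome_h: float = 0.1
    min_marker_px: int = 3

    def __post_init__(self):
        if self.asf_max_radius < 1:
            raise ValueError("asf_max_radius must be >= 1")
        if not (0.0 < self.hdome_h < 1.0):
            raise ValueError("hdome_h must be in (0, 1)")


def asf_filter(img: GrayImage, params: VincentParams = VincentParams()) -> GrayImage:
    """Alternating sequential filter: (open_r then close_r) for r = 1..max."""
    px = img.pixels
    for r in range(1, params.asf_max_radius + 1):
        fp = disk_footprint(r)
        px = ndi.grey_opening(px, footprint=fp, mode="reflect")
        px = ndi.grey_closing(px, footprint=fp, mode="reflect")
    return img.with_pixels(np.clip(px, 0.0, 1.0))


def hdome(img: GrayImage, params: VincentParams = VincentParams()) -> GrayImage:
    """h-dome transform: f - Rec_f(f - h); isolates peaks of height <= h."""
    f = img.pixels
    rec = reconstruction(np.clip(f - params.hdome_h, 0.0, None), f, method="dilation")
    dome = np.clip(f - rec, 0.0, params.hdome_h)
    return img.with_pixels(dome)


def vincent_markers(img: GrayImage, params: VincentParams = VincentParams()):
    """Markers from the difference image: filtered image minus its h-dome.

    That difference equals the grayscale reconstruction of (f - h) under f
    (the h-maxima transform), whose regional maxima are exactly the peaks
    with prominence >= h — so h controls how much low-contrast texture is
    admitted as a cell marker.  A connected plateau counts as a regional
    maximum only if strictly greater than all its neighbors, so a constant
    image yields no markers.  Maxima components smaller than min_marker_px
    are discarded.

    Returns (CentroidSet of marker centers of mass, labeled marker raster).
    """
    diff = img.pixels - hdome(img, params).pixels  # = reconstruction of f-h under f
    if np.ptp(diff) == 0.0:
        maxima = np.zeros(diff.shape, dtype=bool)
    else:
        maxima = local_maxima(diff, connectivity=2)
    lab, n = ndi.label(maxima, structure=ndi.generate_binary_structure(2, 2))
    if n:
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= params.min_marker_px)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        lab = remap[lab]
        n = len(keep)
    centers = ndi.center_of_mass(np.ones_like(lab), lab, index=range(1, n + 1)) if n else []
    points = np.array([(c, r) for r, c in centers], dtype=float).reshape(-1, 2)
    return CentroidSet(image_id=img.id, points=points), lab


def vincent_segment(img: GrayImage, params: VincentParams = VincentParams()) -> SegmentationResult:
    """Full classical pipeline: ASF -> h-dome markers -> watershed -> centroids.

    Every watershed region yields one centroid (the distance-map maximum,
    same convention as the learned pipeline's post-processing); with no
    markers the result is ungradable.
    """
    filtered = asf_filter(img, params)
    _, markers = vincent_markers(filtered, params)
    n_markers = int(markers.max())
    if n_markers == 0:
        return SegmentationResult(
            centroids=CentroidSet(image_id=img.id, points=np.empty((0, 2))),
            border_mask=BorderLabelMap(np.zeros(img.pixels.shape, dtype=np.uint8), image_id=img.id),
            cell_regions=np.zeros(img.pixels.shape, dtype=np.int32),
            gradable=False,
        )
    relief = 1.0 - filtered.pixels
    labels, line = watershed(relief, markers, connectivity=8)
    points, kept, _ = region_centroids(line, labels, n_markers, min_peak=0.0)
    return SegmentationResult(
        centroids=CentroidSet(image_id=img.id, points=np.array(points).reshape(-1, 2)),
        border_mask=BorderLabelMap(line.astype(np.uint8), image_id=img.id),
        cell_regions=labels,
        gradable=len(points) > 0,
    )
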