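"""Training-label synthesis from sparse expert centroid dots.

Expert annotations are one dot per cell.  Dense two-class border label maps
are synthesized by marker-controlled watershed of the preprocessed image:
each dot seeds a basin, the inverted intensity relief makes dark borders
the ridges, and the one-pixel watershed lines become the positive
(cell-border) class.  Image/label pairs are then tiled into 78x78 patches
and augmented by horizontal, vertical, and double mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CentroidSet, GrayImage
from .watershed import watershed

__all__ = [
    "BorderLabelMap",
    "Patch",
    "PatchSet",
    "PATCH_SIZE",
    "centroids_to_labelmap",
    "tile_patches",
    "augment_mirror",
]

PATCH_SIZE = 78

MIRROR_TAGS = ("none", "horizontal", "vertical", "both")


@dataclass(frozen=True)
class BorderLabelMap:
    """Binary raster: 1 = cell-border class, 0 = everything else."""

    mask: np.ndarray
    image_id: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("label map values must be 0 or 1")
        object.__setattr__(self, "mask", m.astype(np.uint8))


@dataclass(frozen=True)
class Patch:
    image_patch: np.ndarray
    label_patch: np.ndarray
    source_id: str
    tile_origin: tuple  # (x, y) of the tile's top-left corner
    mirror: str = "none"


@dataclass(frozen=True)
class PatchSet:
    patches: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "patches", tuple(self.patches))
        for p in self.patches:
            if p.image_patch.shape != p.label_patch.shape:
                raise ValueError("image and label patch dimensions must match")
            if p.mirror not in MIRROR_TAGS:
                raise ValueError(f"unknown mirror tag {p.mirror!r}")

    def __len__(self) -> int:
        return len(self.patches)

    def arrays(self):
        """Stack into (images, labels) float32/int64 arrays for training."""
        if not self.patches:
            raise ValueError("empty PatchSet")
        x = np.stack([p.image_patch for p in self.patches]).astype(np.float32)
        y = np.stack([p.label_patch for p in self.patches]).astype(np.int64)
        return x, y


def _marker_raster(shape, points: np.ndarray) -> np.ndarray:
    """One integer label per dot at its rounded pixel, marker index order.

    Dots that round onto an occupied pixel are dropped with a warning (they
    would denote the same cell twice).
    """
    markers = np.zeros(shape, dtype=np.int32)
    label = 0
    dropped = 0
    for x, y in points:
        r = int(round(y))
        c = int(round(x))
        r = min(max(r, 0), shape[0] - 1)
        c = min(max(c, 0), shape[1] - 1)
        if markers[r, c]:
            dropped += 1
            continue
        label += 1
        markers[r, c] = label
    if dropped:
        warnings.warn(f"{dropped} centroid(s) rounded onto occupied marker pixels; dropped")
    return markers


def centroids_to_labelmap(
    img: GrayImage, dots: CentroidSet, line_width: int = 2
) -> BorderLabelMap:
    """Watershed the inverted intensity relief with one marker per dot.

    ``img`` should already be preprocessed.  With fewer than two dots there
    is no interior watershed line, so an all-zero map is returned with a
    warning.

    The watershed line itself is one pixel wide, but the exact line
    position within a dark border band is ambiguous at the pixel level; a
    one-pixel target makes the border class needlessly hard to hit at a
    fixed probability threshold.  The label line is therefore thickened to
    ``line_width`` pixels (default 2, about the width of the dark border
    band itself) by dilation.
    """
    if len(dots) < 2:
        warnings.warn(
            f"image {img.id!r}: {len(dots)} centroid(s); no watershed line exists"
        )
        return BorderLabelMap(np.zeros(img.pixels.shape, dtype=np.uint8), image_id=img.id)
    markers = _marker_raster(img.pixels.shape, dots.points)
    relief = 1.0 - img.pixels  # bright cell interiors become basins
    _, line = watershed(relief, markers, connectivity=8)
    if line_width > 1:
        from scipy import ndimage as ndi

        line = ndi.binary_dilation(line, structure=np.ones((line_width, line_width)))
    return BorderLabelMap(line.astype(np.uint8), image_id=img.id)


def tile_patches(img: GrayImage, label: BorderLabelMap, size: int = PATCH_SIZE) -> PatchSet:
    """Non-overlapping size x size tiles anchored at (0, 0).

    Partial tiles at the right/bottom edges are discarded; image and label
    are tiled identically.
    """
    if img.pixels.shape != label.mask.shape:
        raise ValueError("image and label map must share dimensions")
    h, w = img.pixels.shape
    patches = []
    for ty in range(h // size):
        for tx in range(w // size):
            y0, x0 = ty * size, tx * size
            patches.append(
                Patch(
                    image_patch=img.pixels[y0 : y0 + size, x0 : x0 + size].copy(),
                    label_patch=label.mask[y0 : y0 + size, x0 : x0 + size].copy(),
                    source_id=img.id,
                    tile_origin=(x0, y0),
                )
            )
    return PatchSet(patches)


def _mirror(a: np.ndarray, tag: str) -> np.ndarray:
    if tag == "none":
        return a.copy()
    if tag == "horizontal":
        return a[:, ::-1].copy()
    if tag == "vertical":
        return a[::-1, :].copy()
    if tag == "both":
        return a[::-1, ::-1].copy()
    raise ValueError(f"unknown mirror tag {tag!r}")


def augment_mirror(patches: PatchSet) -> PatchSet:
    """Four-way mirror augmentation: original, horizontal, vertical, both."""
    out = []
    for p in patches.patches:
        for tag in MIRROR_TAGS:
            out.append(
                Patch(
                    image_patch=_mirror(p.image_patch, tag),
                    label_patch=_mirror(p.label_patch, tag),
                    source_id=p.source_id,
                    tile_origin=p.tile_origin,
                    mirror=tag,
                )
            )
    return PatchSet(out)
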