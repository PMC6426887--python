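"""Endothelial cell density from centroids via Voronoi tessellation.

Density (cells/mm^2) is the inverse of the median Voronoi cell area over
the *interior* centroids.  A centroid is a border centroid — and excluded —
when its Voronoi cell is unbounded or touches the image frame, because such
a cell's area is an artifact of the field of view, not of cell size.
The pixel-to-micron calibration is an explicit parameter; nothing in the
imagery itself fixes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from scipy.spatial._qhull import QhullError
from shapely.geometry import Polygon, box

from .io import CentroidSet

__all__ = ["ScaleCalibration", "VoronoiCell", "DensityEstimate", "voronoi_areas", "estimate_density"]


@dataclass(frozen=True)
class ScaleCalibration:
    microns_per_pixel: float = 1.0

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")


@dataclass(frozen=True)
class VoronoiCell:
    centroid: tuple  # (x, y)
    area_px2: float  # NaN for border cells
    is_border: bool


@dataclass(frozen=True)
class DensityEstimate:
    cells_per_mm2: float
    median_area_px2: float
    n_interior: int
    n_excluded_border: int
    gradable: bool
    image_id: str = ""


def voronoi_areas(centroids: CentroidSet, frame: tuple) -> list:
    """Voronoi cells of the centroids clipped to ``frame`` = (width, height).

    Returns one :class:`VoronoiCell` per centroid, in input order.  With
    fewer than four points, or a degenerate (e.g. collinear) configuration,
    every centroid is flagged border and no areas are reported.
    """
    width, height = frame
    pts = centroids.points
    n = len(pts)
    if n < 4:
        return [VoronoiCell(tuple(p), math.nan, True) for p in pts]
    try:
        vor = Voronoi(pts)
    except QhullError:
        return [VoronoiCell(tuple(p), math.nan, True) for p in pts]
    frame_poly = box(0.0, 0.0, width - 1.0, height - 1.0)
    out = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            out.append(VoronoiCell(tuple(pts[i]), math.nan, True))
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid or poly.is_empty:
            out.append(VoronoiCell(tuple(pts[i]), math.nan, True))
            continue
        clipped = poly.intersection(frame_poly)
        is_border = not poly.within(frame_poly.buffer(-1e-9))
        area = math.nan if is_border else float(clipped.area)
        out.append(VoronoiCell(tuple(pts[i]), area, is_border))
    return out


def estimate_density(
    centroids: CentroidSet, frame: tuple, scale: ScaleCalibration = ScaleCalibration()
) -> DensityEstimate:
    """cells/mm^2 = 1 / (median interior Voronoi area in mm^2).

    An empty interior set (including an empty centroid set) yields an
    ungradable estimate with density 0.
    """
    cells = voronoi_areas(centroids, frame)
    interior = [c.area_px2 for c in cells if not c.is_border]
    n_border = sum(1 for c in cells if c.is_border)
    if not interior:
        return DensityEstimate(0.0, math.nan, 0, n_border, False, image_id=centroids.image_id)
    median_px2 = float(np.median(interior))
    mm_per_px = scale.microns_per_pixel / 1000.0
    density = 1.0 / (median_px2 * mm_per_px**2)
    return DensityEstimate(
        cells_per_mm2=density,
        median_area_px2=median_px2,
        n_interior=len(interior),
        n_excluded_border=n_border,
        gradable=True,
        image_id=centroids.image_id,
    )
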