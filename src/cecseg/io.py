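"""Reading and writing images, centroid tables, and corpus manifests.

Conventions used throughout the package:

* images are 2-D ``float64`` rasters with intensities in ``[0, 1]``;
* coordinates are 0-based with ``x`` the column (from the left) and ``y``
  the row (from the top); centroids may be sub-pixel;
* centroid tables are CSV with header ``image_id,x,y``;
* corpus manifests are CSV with header
  ``image_id,split,ungradable,guttae,annotation_path``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "GrayImage",
    "CentroidSet",
    "ManifestRecord",
    "CorpusManifest",
    "read_image",
    "write_image",
    "read_centroids",
    "write_centroids",
    "read_manifest",
    "write_manifest",
    "split_manifest",
]

# ITU-R BT.601 luma weights, used when a color image sneaks in.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A grayscale raster with intensities normalized to [0, 1]."""

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"GrayImage requires a non-empty 2-D raster, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("GrayImage pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("GrayImage pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels=pixels, id=self.id)


@dataclass(frozen=True)
class CentroidSet:
    """Per-image list of sub-pixel (x, y) cell-center coordinates."""

    image_id: str
    points: np.ndarray  # shape (n, 2), columns (x, y)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if pts.size and len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError(f"duplicate centroid(s) in image {self.image_id!r}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, image: GrayImage) -> None:
        """Raise if any point lies outside ``image``'s pixel bounds."""
        if not len(self):
            return
        x, y = self.points[:, 0], self.points[:, 1]
        bad = (x < 0) | (x > image.width - 1) | (y < 0) | (y > image.height - 1)
        if bad.any():
            rows = np.flatnonzero(bad).tolist()
            raise ValueError(
                f"centroids out of bounds for image {image.id!r} "
                f"({image.width}x{image.height}): rows {rows}"
            )


@dataclass(frozen=True)
class ManifestRecord:
    image_id: str
    split: str = "validation"  # "train" | "validation"
    ungradable: bool = False
    guttae: bool = False
    annotation_path: str = ""


@dataclass(frozen=True)
class CorpusManifest:
    records: tuple = field(default_factory=tuple)

    def __post_init__(self):
        recs = tuple(self.records)
        ids = [r.image_id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest image_ids must be unique")
        for r in recs:
            if r.split not in ("train", "validation"):
                raise ValueError(f"unknown split {r.split!r} for {r.image_id!r}")
            if r.ungradable and r.annotation_path:
                raise ValueError(
                    f"ungradable record {r.image_id!r} must not carry an annotation"
                )
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def gradable(self) -> tuple:
        return tuple(r for r in self.records if not r.ungradable)

    def subset(self, split: str) -> tuple:
        return tuple(r for r in self.records if r.split == split)


def read_image(path: str) -> GrayImage:
    """Read an 8/16-bit grayscale (or color, converted by luminance) image.

    Intensities are linearly rescaled to [0, 1] by the format's full range.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif arr.dtype == np.uint8:
        scale = 255.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype} in {path!r}")
    image_id = os.path.splitext(os.path.basename(path))[0]
    return GrayImage(np.clip(arr / scale, 0.0, 1.0), id=image_id)


def write_image(img: GrayImage, path: str) -> None:
    """Write as 8-bit grayscale PNG/TIFF (by extension)."""
    arr = np.rint(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_centroids(path: str, image: GrayImage) -> CentroidSet:
    """Read a centroid CSV (``image_id,x,y``) and validate against ``image``.

    An empty table is legal and denotes an ungradable image.
    """
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid table {path!r} lacks column(s) {sorted(missing)}")
    cs = CentroidSet(image_id=image.id, points=df[["x", "y"]].to_numpy(dtype=np.float64))
    cs.validate_bounds(image)
    return cs


def write_centroids(cs: CentroidSet, path: str) -> None:
    df = pd.DataFrame(
        {
            "image_id": [cs.image_id] * len(cs),
            "x": cs.points[:, 0] if len(cs) else [],
            "y": cs.points[:, 1] if len(cs) else [],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path: str) -> CorpusManifest:
    df = pd.read_csv(path, keep_default_na=False)
    records = [
        ManifestRecord(
            image_id=str(row.image_id),
            split=str(row.split),
            ungradable=_as_bool(row.ungradable),
            guttae=_as_bool(row.guttae),
            annotation_path=str(row.annotation_path),
        )
        for row in df.itertuples()
    ]
    return CorpusManifest(records)


def write_manifest(manifest: CorpusManifest, path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "split": r.split,
                "ungradable": int(r.ungradable),
                "guttae": int(r.guttae),
                "annotation_path": r.annotation_path,
            }
            for r in manifest.records
        ],
        columns=["image_id", "split", "ungradable", "guttae", "annotation_path"],
    )
    df.to_csv(path, index=False)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def split_manifest(manifest: CorpusManifest, n_train: int, seed: int) -> CorpusManifest:
    """Randomly assign ``n_train`` gradable records to the training split.

    Ungradable records are never assigned to training; everything not chosen
    for training is marked validation.  Deterministic given ``seed``.
    """
    gradable_idx = [i for i, r in enumerate(manifest.records) if not r.ungradable]
    if n_train > len(gradable_idx):
        raise ValueError(
            f"n_train={n_train} exceeds the {len(gradable_idx)} gradable records"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(gradable_idx, size=n_train, replace=False).tolist()) if n_train else set()
    records = [
        replace(r, split="train" if i in chosen else "validation")
        for i, r in enumerate(manifest.records)
    ]
    return CorpusManifest(records)
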