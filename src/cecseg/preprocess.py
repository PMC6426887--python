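"""Fixed preprocessing chain: Gaussian blur -> white top-hat -> histogram equalization.

The same chain is applied before training-label synthesis and before
inference, so the network always sees contrast-normalized mosaics in which
the dark inter-cellular borders are local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure

from .io import GrayImage

__all__ = ["PreprocessParams", "gaussian_blur", "top_hat", "equalize_hist", "preprocess", "disk_footprint"]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    blur_radius is advisory: the Gaussian kernel half-width is
    ``max(blur_radius, ceil(3 * blur_sigma))`` so that the kernel always
    supports the requested standard deviation.  The top-hat structuring
    element is a disc whose radius should exceed one cell diameter so that
    the top-hat flattens illumination gradients, not the cell mosaic.
    """

    blur_radius: int = 1
    blur_sigma: float = 2.0
    tophat_radius: int = 15
    equalize_bins: int = 256

    def __post_init__(self):
        if self.blur_radius < 0 or self.tophat_radius < 0:
            raise ValueError("radii must be >= 0")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disc of the given radius (Euclidean, centre included)."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def gaussian_blur(img: GrayImage, params: PreprocessParams = PreprocessParams()) -> GrayImage:
    """Gaussian blur with a normalized, truncated kernel and reflective edges."""
    half = max(params.blur_radius, math.ceil(3.0 * params.blur_sigma))
    out = ndi.gaussian_filter(
        img.pixels, sigma=params.blur_sigma, truncate=half / params.blur_sigma, mode="reflect"
    )
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def top_hat(img: GrayImage, params: PreprocessParams = PreprocessParams()) -> GrayImage:
    """White top-hat: image minus its grayscale opening by a disc.

    Keeps bright structures smaller than the disc (the cells) and removes
    slowly varying background, so the result is >= 0 everywhere and
    pointwise <= the input.
    """
    footprint = disk_footprint(params.tophat_radius)
    opened = ndi.grey_opening(img.pixels, footprint=footprint, mode="reflect")
    out = img.pixels - opened
    # float round-off can leave tiny negatives
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def equalize_hist(img: GrayImage, params: PreprocessParams = PreprocessParams()) -> GrayImage:
    """Global histogram equalization (monotone CDF mapping) onto [0, 1]."""
    px = img.pixels
    if np.ptp(px) == 0.0:  # degenerate CDF: leave the constant image alone
        return img
    out = exposure.equalize_hist(px, nbins=params.equalize_bins)
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def preprocess(img: GrayImage, params: PreprocessParams = PreprocessParams()) -> GrayImage:
    """Blur, then top-hat, then equalize — in that order."""
    return equalize_hist(top_hat(gaussian_blur(img, params), params), params)
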