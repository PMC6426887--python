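"""scikit-learn style estimators wrapping the two segmentation pipelines.

``UNetBorderSegmenter`` is fit on images plus per-image centroid dots
(label maps are synthesized internally) and predicts full segmentation
results; ``VincentSegmenter`` is the classical no-training baseline with
the same predict surface.  Both follow the sklearn estimator contract
(``get_params``/``set_params``, fitted attributes with trailing
underscores, ``check_is_fitted``-compatible), so they compose with sklearn
model-selection utilities that treat X as an opaque sequence.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .density import ScaleCalibration, estimate_density
from .io import CentroidSet, GrayImage
from .labels import PATCH_SIZE, augment_mirror, centroids_to_labelmap, tile_patches, PatchSet
from .postprocess import PostprocessParams, SegmentationResult, binarize, extract_centroids, remove_small_objects
from .preprocess import PreprocessParams, preprocess
from .unet import UNetConfig, build_model, predict_probability_map, train
from .vincent import VincentParams, vincent_segment

__all__ = ["UNetBorderSegmenter", "VincentSegmenter"]


def _as_gray(img, idx: int) -> GrayImage:
    if isinstance(img, GrayImage):
        return img
    return GrayImage(np.asarray(img, dtype=float), id=f"image_{idx:04d}")


def _as_centroids(y, image: GrayImage) -> CentroidSet:
    if isinstance(y, CentroidSet):
        return y
    return CentroidSet(image_id=image.id, points=np.asarray(y, dtype=float).reshape(-1, 2))


class UNetBorderSegmenter(BaseEstimator):
    """Centroid-supervised U-Net border segmenter.

    fit(X, y): X is a sequence of grayscale images (2-D arrays in [0, 1] or
    :class:`GrayImage`), y the matching sequence of cell-centroid sets.
    Dense border label maps are synthesized from the dots by
    marker-controlled watershed, tiled into mirrored patches, and the
    network is trained on pixel-wise cross-entropy.

    predict(X) returns one :class:`SegmentationResult` per image
    (centroids, cleaned border mask, cell regions, gradable flag).
    """

    def __init__(
        self,
        depth: int = 3,
        root_features: int = 26,
        epochs: int = 150,
        iterations_per_epoch: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        patch_size: int = PATCH_SIZE,
        blur_radius: int = 1,
        blur_sigma: float = 2.0,
        tophat_radius: int = 15,
        prob_threshold: float = 0.60,
        min_object_px: int = 1000,
        min_peak_separation: float = 2.0,
        microns_per_pixel: float = 1.0,
        random_state: int = 0,
    ):
        self.depth = depth
        self.root_features = root_features
        self.epochs = epochs
        self.iterations_per_epoch = iterations_per_epoch
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.blur_radius = blur_radius
        self.blur_sigma = blur_sigma
        self.tophat_radius = tophat_radius
        self.prob_threshold = prob_threshold
        self.min_object_px = min_object_px
        self.min_peak_separation = min_peak_separation
        self.microns_per_pixel = microns_per_pixel
        self.random_state = random_state

    # -- parameter bundles --------------------------------------------------

    def _preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            blur_radius=self.blur_radius,
            blur_sigma=self.blur_sigma,
            tophat_radius=self.tophat_radius,
        )

    def _unet_config(self) -> UNetConfig:
        return UNetConfig(
            depth=self.depth,
            root_features=self.root_features,
            epochs=self.epochs,
            iterations_per_epoch=self.iterations_per_epoch,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.random_state,
        )

    def _postprocess_params(self) -> PostprocessParams:
        return PostprocessParams(
            prob_threshold=self.prob_threshold,
            min_object_px=self.min_object_px,
            min_peak_separation=self.min_peak_separation,
        )

    # -- estimator API ------------------------------------------------------

    def build_training_patches(self, X, y) -> PatchSet:
        """Preprocess, synthesize label maps, tile, and mirror-augment."""
        pp = self._preprocess_params()
        patches = []
        for i, (img, dots) in enumerate(zip(X, y)):
            gimg = _as_gray(img, i)
            pre = preprocess(gimg, pp)
            label = centroids_to_labelmap(pre, _as_centroids(dots, gimg))
            tiles = tile_patches(pre, label, size=self.patch_size)
            patches.extend(augment_mirror(tiles).patches)
        return PatchSet(patches)

    def fit(self, X, y):
        patch_set = self.build_training_patches(X, y)
        if len(patch_set) == 0:
            raise ValueError("no training patches: images smaller than patch_size?")
        cfg = self._unet_config()
        self.model_ = build_model(cfg)
        self.history_ = train(self.model_, patch_set, cfg)
        self.n_patches_ = len(patch_set)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("UNetBorderSegmenter is not fitted yet; call fit first")

    def predict_proba(self, X):
        """Per-image border probability maps (on preprocessed images)."""
        self._check_fitted()
        pp = self._preprocess_params()
        return [
            predict_probability_map(self.model_, preprocess(_as_gray(img, i), pp))
            for i, img in enumerate(X)
        ]

    def predict(self, X):
        """Per-image SegmentationResult (centroids + gradable flag)."""
        self._check_fitted()
        post = self._postprocess_params()
        out = []
        for pm in self.predict_proba(X):
            mask = remove_small_objects(binarize(pm, post), post)
            out.append(extract_centroids(mask, post))
        return out

    def predict_density(self, X):
        """Per-image Voronoi density estimates from the predicted centroids."""
        results = self.predict(X)
        scale = ScaleCalibration(self.microns_per_pixel)
        out = []
        for img, res in zip(X, results):
            gimg = _as_gray(img, 0)
            out.append(estimate_density(res.centroids, (gimg.width, gimg.height), scale))
        return out


class VincentSegmenter(BaseEstimator):
    """Classical ASF -> h-dome -> marker watershed segmenter (no training)."""

    def __init__(
        self,
        asf_max_radius: int = 2,
        hdome_h: float = 0.1,
        min_marker_px: int = 3,
        microns_per_pixel: float = 1.0,
    ):
        self.asf_max_radius = asf_max_radius
        self.hdome_h = hdome_h
        self.min_marker_px = min_marker_px
        self.microns_per_pixel = microns_per_pixel

    def _params(self) -> VincentParams:
        return VincentParams(
            asf_max_radius=self.asf_max_radius,
            hdome_h=self.hdome_h,
            min_marker_px=self.min_marker_px,
        )

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def predict(self, X):
        params = self._params()
        return [vincent_segment(_as_gray(img, i), params) for i, img in enumerate(X)]

    def predict_density(self, X):
        scale = ScaleCalibration(self.microns_per_pixel)
        out = []
        for i, (img, res) in enumerate(zip(X, self.predict(X))):
            gimg = _as_gray(img, i)
            out.append(estimate_density(res.centroids, (gimg.width, gimg.height), scale))
        return out
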