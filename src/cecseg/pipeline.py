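"""End-to-end pipeline runs: train, segment, baseline, evaluate.

These functions are the library surface behind the CLI subcommands.  Every
run writes a machine-readable run manifest (config digest, seed, package
version) next to its outputs, and per-image failures are logged and
recorded without aborting the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .config import PipelineConfig
from .density import estimate_density
from .estimators import UNetBorderSegmenter, VincentSegmenter
from .evaluation import density_agreement, match_centroids, ungradable_crosstab
from .unet import UNet

log = logging.getLogger("cecseg")

__all__ = ["run_train", "run_segment", "run_vincent", "run_evaluate", "write_run_manifest"]


def write_run_manifest(out_dir: str, config: PipelineConfig, command: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    payload = {
        "command": command,
        "config_digest": config.digest(),
        "seed": config.seed,
        "cecseg_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    with open(os.path.join(out_dir, f"run_{command}.json"), "w") as fh:
        json.dump(payload, fh, indent=2)


def _load_corpus(manifest: cio.CorpusManifest, images_dir: str, records):
    """Yield (GrayImage, CentroidSet|None) for the given manifest records."""
    for rec in records:
        path = os.path.join(images_dir, f"{rec.image_id}.png")
        img = cio.read_image(path)
        dots = None
        if rec.annotation_path:
            ann = rec.annotation_path
            if not os.path.isabs(ann) and not os.path.exists(ann):
                ann = os.path.join(images_dir, os.path.basename(ann))
            dots = cio.read_centroids(ann, img)
        yield img, dots


def _segmenter_from_config(config: PipelineConfig) -> UNetBorderSegmenter:
    pp, uc, po = config.preprocess, config.unet, config.postprocess
    return UNetBorderSegmenter(
        depth=uc.depth,
        root_features=uc.root_features,
        epochs=uc.epochs,
        iterations_per_epoch=uc.iterations_per_epoch,
        learning_rate=uc.learning_rate,
        batch_size=uc.batch_size,
        blur_radius=pp.blur_radius,
        blur_sigma=pp.blur_sigma,
        tophat_radius=pp.tophat_radius,
        prob_threshold=po.prob_threshold,
        min_object_px=po.min_object_px,
        min_peak_separation=po.min_peak_separation,
        microns_per_pixel=config.density.microns_per_pixel,
        random_state=config.stage_seed("unet"),
    )


def run_train(config: PipelineConfig, manifest: cio.CorpusManifest, images_dir: str, out_dir: str):
    """Preprocess -> label synthesis -> patching -> training; write checkpoint.

    Only gradable training-split images with annotations are used.
    """
    os.makedirs(out_dir, exist_ok=True)
    records = [r for r in manifest.subset("train") if not r.ungradable and r.annotation_path]
    if not records:
        raise ValueError("manifest has no gradable, annotated training images")
    images, dots = [], []
    for img, ann in _load_corpus(manifest, images_dir, records):
        images.append(img)
        dots.append(ann)
    seg = _segmenter_from_config(config)
    seg.fit(images, dots)
    ckpt = os.path.join(out_dir, "model.npz")
    seg.model_.save(ckpt)
    curve = pd.DataFrame(
        {
            "epoch": np.arange(1, len(seg.history_.loss) + 1),
            "loss": seg.history_.loss,
            "pixel_accuracy": seg.history_.pixel_accuracy,
        }
    )
    curve.to_csv(os.path.join(out_dir, "training_curve.csv"), index=False)
    write_run_manifest(out_dir, config, "train")
    log.info("trained on %d images (%d patches); checkpoint at %s", len(images), seg.n_patches_, ckpt)
    return seg, ckpt


def _segment_batch(segmenter, images, config: PipelineConfig, out_dir: str, tag: str):
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for img in images:
        try:
            res = segmenter.predict([img])[0]
            est = estimate_density(res.centroids, (img.width, img.height), config.density)
            cio.write_centroids(res.centroids, os.path.join(out_dir, f"{img.id}_{tag}_centroids.csv"))
            rows.append(
                {
                    "image_id": img.id,
                    "cells_per_mm2": est.cells_per_mm2,
                    "median_area_px2": est.median_area_px2,
                    "n_interior": est.n_interior,
                    "n_excluded_border": est.n_excluded_border,
                    "gradable": int(res.gradable),
                }
            )
        except Exception as exc:  # keep the batch alive, record the failure
            log.error("image %s failed: %s", img.id, exc)
            rows.append(
                {
                    "image_id": img.id,
                    "cells_per_mm2": float("nan"),
                    "median_area_px2": float("nan"),
                    "n_interior": 0,
                    "n_excluded_border": 0,
                    "gradable": 0,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(out_dir, f"density_{tag}.csv"), index=False)
    write_run_manifest(out_dir, config, tag)
    return df


def run_segment(config: PipelineConfig, model: UNet, images, out_dir: str):
    """U-Net path: probability map -> post-processing -> centroids -> density."""
    seg = _segmenter_from_config(config)
    seg.model_ = model
    return _segment_batch(seg, images, config, out_dir, "unet")


def run_vincent(config: PipelineConfig, images, out_dir: str):
    """Classical path on the raw images."""
    v = config.vincent
    seg = VincentSegmenter(
        asf_max_radius=v.asf_max_radius,
        hdome_h=v.hdome_h,
        min_marker_px=v.min_marker_px,
        microns_per_pixel=config.density.microns_per_pixel,
    ).fit()
    return _segment_batch(seg, images, config, out_dir, "vincent")


def run_evaluate(pred_sets, truth_sets, pred_density, truth_density, tolerance_px: float, out_dir: str):
    """Match centroids per image and summarize density agreement.

    Writes a per-image CSV and a JSON summary; returns (DataFrame, summary).
    Per-image NaN metrics are excluded from the corpus means.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for pred, truth in zip(pred_sets, truth_sets):
        rep = match_centroids(pred, truth, tolerance_px)
        rows.append(dataclasses.asdict(rep))
    df = pd.DataFrame(rows)
    agreement = density_agreement(
        [(t, p) for t, p in zip(truth_density, pred_density)]
    )
    crosstab = ungradable_crosstab(
        [(len(t) == 0, len(p) == 0) for p, t in zip(pred_sets, truth_sets)]
    )
    summary = {
        "n_images": int(len(df)),
        "mean_recall": float(np.nanmean(df["recall"])) if len(df) else float("nan"),
        "mean_precision": float(np.nanmean(df["precision"])) if len(df) else float("nan"),
        "r_squared": agreement.r_squared,
        "pct_within_250": agreement.pct_within_250,
        "pct_within_500": agreement.pct_within_500,
        "ungradable_crosstab": crosstab.tolist(),
        "na_rule": "per-image NaN metrics excluded from corpus means",
    }
    df.to_csv(os.path.join(out_dir, "evaluation.csv"), index=False)
    with open(os.path.join(out_dir, "evaluation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return df, summary
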