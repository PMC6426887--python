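import numpy as np
import pytest

from cecseg.io import GrayImage
from cecseg.labels import BorderLabelMap, Patch, PatchSet
from cecseg.unet import (
    UNet,
    UNetConfig,
    build_model,
    cross_entropy,
    predict_probability_map,
    train,
)


def _expected_param_count(depth, root, in_ch, n_classes):
    """Layer-by-layer hand tally of the architecture's parameters."""
    total = 0
    c_in = in_ch
    for lvl in range(depth):
        c_out = root * 2**lvl
        total += c_out * c_in * 9 + c_out  # conv 3x3 + bias
        total += c_out * c_out * 9 + c_out
        c_in = c_out
    for lvl in range(depth - 2, -1, -1):
        c_hi = root * 2 ** (lvl + 1)
        c_out = root * 2**lvl
        total += c_hi * c_out * 4 + c_out  # 2x2 transposed conv
        total += c_out * (2 * c_out) * 9 + c_out
        total += c_out * c_out * 9 + c_out
    total += n_classes * root + n_classes  # final 1x1
    return total


@pytest.mark.parametrize("depth,root", [(3, 26), (3, 8), (2, 4)])
def test_parameter_count_matches_closed_form(depth, root):
    cfg = UNetConfig(depth=depth, root_features=root)
    model = build_model(cfg)
    assert model.n_parameters == _expected_param_count(depth, root, 1, 2)


def test_seeded_initialization_is_reproducible():
    cfg = UNetConfig(root_features=4, seed=123)
    a, b = build_model(cfg), build_model(cfg)
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    c = build_model(UNetConfig(root_features=4, seed=124))
    assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


def test_softmax_channels_sum_to_one_and_shape_follows_input():
    model = build_model(UNetConfig(root_features=4, seed=0))
    rng = np.random.default_rng(0)
    for shape in [(40, 40), (38, 50), (79, 41)]:  # incl. non-multiples of 4
        img = GrayImage(rng.random(shape))
        pm = predict_probability_map(model, img)
        assert pm.probs.shape == shape
        assert pm.probs.min() >= 0.0 and pm.probs.max() <= 1.0
        # two-channel softmax: background probability is the complement
        logits = model.forward(img.pixels.astype(np.float32)[None, None])
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(p[0, 0] + p[0, 1], 1.0, atol=1e-6)


def test_prediction_deterministic():
    model = build_model(UNetConfig(root_features=4, seed=1))
    img = GrayImage(np.random.default_rng(2).random((40, 40)))
    a = predict_probability_map(model, img).probs
    b = predict_probability_map(model, img).probs
    assert np.array_equal(a, b)


def _toy_patches(rng, n=8, size=40, border_fn=None):
    patches = []
    for _ in range(n):
        img = rng.random((size, size)) * 0.3 + 0.5
        label = np.zeros((size, size), dtype=np.uint8)
        if border_fn is not None:
            label = border_fn(size)
            img = np.where(label, 0.1, img)
        patches.append(
            Patch(image_patch=img, label_patch=label, source_id="t", tile_origin=(0, 0))
        )
    return PatchSet(patches)


def _grid_label(size):
    m = np.zeros((size, size), dtype=np.uint8)
    m[::10, :] = 1
    m[:, ::10] = 1
    return m


class TestTraining:
    def test_loss_decreases_by_an_order_of_magnitude_when_overfitting(self):
        rng = np.random.default_rng(0)
        patches = _toy_patches(rng, n=8, border_fn=_grid_label)
        cfg = UNetConfig(root_features=4, epochs=10, iterations_per_epoch=20, batch_size=4, seed=0)
        model = build_model(cfg)
        hist = train(model, patches, cfg)
        assert hist.loss[-1] < 0.1 * hist.loss[0]

    def test_all_background_labels_drive_border_probability_down(self):
        rng = np.random.default_rng(1)
        patches = _toy_patches(rng, n=4)
        cfg = UNetConfig(root_features=4, epochs=4, iterations_per_epoch=50, batch_size=4, seed=0)
        model = build_model(cfg)
        train(model, patches, cfg)
        pm = predict_probability_map(model, GrayImage(rng.random((40, 40)) * 0.3 + 0.5))
        assert pm.probs.max() < 0.1

    def test_history_length_matches_epochs(self):
        rng = np.random.default_rng(2)
        patches = _toy_patches(rng, n=4)
        cfg = UNetConfig(root_features=2, epochs=3, iterations_per_epoch=2, batch_size=2, seed=0)
        model = build_model(cfg)
        hist = train(model, patches, cfg)
        assert len(hist.loss) == 3
        assert len(hist.pixel_accuracy) == 3

    def test_empty_patchset_rejected(self):
        cfg = UNetConfig(root_features=2)
        with pytest.raises(ValueError, match="empty"):
            train(build_model(cfg), PatchSet([]), cfg)

    def test_overfit_single_patch_reconstructs_its_label(self):
        rng = np.random.default_rng(3)
        label = _grid_label(40)
        img = np.where(label, 0.1, 0.8) + rng.normal(0, 0.02, (40, 40))
        patch = Patch(
            image_patch=np.clip(img, 0, 1), label_patch=label, source_id="o", tile_origin=(0, 0)
        )
        cfg = UNetConfig(root_features=6, epochs=5, iterations_per_epoch=30, batch_size=1, seed=0)
        model = build_model(cfg)
        train(model, PatchSet([patch]), cfg)
        pm = predict_probability_map(model, GrayImage(np.clip(img, 0, 1)))
        thresholded = (pm.probs >= 0.5).astype(np.uint8)
        assert np.abs(thresholded.astype(float) - label).mean() < 0.05


def test_mirror_equivariance_with_symmetric_kernels():
    """With left-right symmetric kernels and no input padding asymmetry the
    architecture commutes with horizontal mirroring."""
    model = build_model(UNetConfig(root_features=4, seed=5))
    for k, v in model.params.items():
        if v.ndim == 4:
            model.params[k] = 0.5 * (v + v[..., ::-1])
    rng = np.random.default_rng(6)
    img = rng.random((40, 40)).astype(np.float32)
    a = predict_probability_map(model, GrayImage(img)).probs
    b = predict_probability_map(model, GrayImage(img[:, ::-1].copy())).probs
    assert np.allclose(a, b[:, ::-1], atol=1e-5)


def test_checkpoint_roundtrip(tmp_path):
    model = build_model(UNetConfig(root_features=4, seed=7))
    path = str(tmp_path / "m.npz")
    model.save(path)
    back = UNet.load(path)
    assert back.config == model.config
    for k in model.params:
        assert np.array_equal(back.params[k], model.params[k])


def test_non_finite_loss_aborts():
    rng = np.random.default_rng(8)
    patches = _toy_patches(rng, n=2)
    cfg = UNetConfig(root_features=2, epochs=1, iterations_per_epoch=3, batch_size=2,
                     learning_rate=1e6, seed=0)
    model = build_model(cfg)
    with pytest.raises((FloatingPointError, ValueError)):
        with np.errstate(over="ignore", invalid="ignore"):
            train(model, patches, cfg)
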