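"""Two-class U-Net for cell-border probability maps, implemented in NumPy.

The network is the standard encoder/decoder with skip connections: 3x3
convolutions (two per level), ReLU, 2x2 max-pooling on the way down, 2x2
transposed convolutions on the way up, and a final 1x1 convolution onto two
classes (cell border vs. no cell border).  Convolutions are "same"-padded
so the probability map has the raster size of the input; inputs whose sides
are not divisible by 2**(depth-1) are reflect-padded up and the output is
cropped back.

Training minimizes unweighted pixel-wise two-class cross-entropy with Adam.
Everything — parameter initialization, batch shuffling — is deterministic
given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import GrayImage
from .labels import PatchSet

__all__ = [
    "UNetConfig",
    "ProbabilityMap",
    "UNet",
    "build_model",
    "train",
    "predict_probability_map",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and training schedule.

    ``iterations_per_epoch`` optimizer steps are taken per epoch; the loss
    history carries one entry per epoch.
    """

    depth: int = 3
    root_features: int = 26
    in_channels: int = 1
    n_classes: int = 2
    iterations_per_epoch: int = 200
    epochs: int = 150
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.root_features < 1:
            raise ValueError("depth and root_features must be >= 1")
        if self.n_classes != 2:
            raise ValueError("this segmenter is two-class (border vs. non-border)")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel cell-border probability in [0, 1]."""

    probs: np.ndarray
    image_id: str = ""

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("probabilities must be finite and in [0, 1]")
        object.__setattr__(self, "probs", p)


# ---------------------------------------------------------------------------
# layer primitives (float32 throughout)

def _conv3(x, w, b):
    """'Same' 3x3 correlation. x:(N,C,H,W), w:(F,C,3,3) -> (N,F,H,W)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    y = np.einsum("nchwab,fcab->nfhw", win, w, optimize=True)
    return y + b[None, :, None, None]


def _conv3_backward(x, w, dy):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dw = np.einsum("nchwab,nfhw->fcab", win, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,3,3)
    dx = _conv3(dy, w_flip, np.zeros(w.shape[1], dtype=w.dtype))
    return dx, dw, db


def _conv1(x, w, b):
    """1x1 convolution. w:(F,C)."""
    return np.einsum("nchw,fc->nfhw", x, w, optimize=True) + b[None, :, None, None]


def _conv1_backward(x, w, dy):
    dw = np.einsum("nchw,nfhw->fc", x, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("nfhw,fc->nchw", dy, w, optimize=True)
    return dx, dw, db


def _maxpool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # break plateau ties: keep only the first maximal position per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    flat = flat & first
    mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return y, mask


def _maxpool2_backward(mask, dy):
    n, c, hh, _, ww, _ = mask.shape
    dx = mask * dy[:, :, :, None, :, None]
    return dx.reshape(n, c, hh * 2, ww * 2)


def _upconv2(x, w, b):
    """2x2 stride-2 transposed convolution. x:(N,C,H,W), w:(C,F,2,2)."""
    y = np.einsum("ncij,cfab->nfiajb", x, w, optimize=True)
    n, f = x.shape[0], w.shape[1]
    h, wd = x.shape[2], x.shape[3]
    return y.reshape(n, f, 2 * h, 2 * wd) + b[None, :, None, None]


def _upconv2_backward(x, w, dy):
    n, c, h, wd = x.shape
    f = w.shape[1]
    dyr = dy.reshape(n, f, h, 2, wd, 2)
    dw = np.einsum("ncij,nfiajb->cfab", x, dyr, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("nfiajb,cfab->ncij", dyr, w, optimize=True)
    return dx, dw, db


def _softmax(logits):
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean pixel-wise CE and its gradient w.r.t. the logits."""
    p = _softmax(logits)
    n, _, h, w = logits.shape
    idx = np.arange(n)[:, None, None], labels, np.arange(h)[None, :, None], np.arange(w)[None, None, :]
    picked = p[idx[0], idx[1], idx[2], idx[3]]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    onehot = np.zeros_like(p)
    onehot[idx[0], idx[1], idx[2], idx[3]] = 1.0
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------


class UNet:
    """Parameter container plus explicit forward/backward passes."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.params: dict = {}
        self._adam_m: dict = {}
        self._adam_v: dict = {}
        self._adam_t = 0
        self._init_params()

    # -- construction -------------------------------------------------------

    def _add(self, name, shape, fan_in, rng):
        self.params[name] = (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        bias = name.replace("w", "b", 1)
        self.params[bias] = np.zeros(shape[0] if name.startswith(("wc", "wo")) else shape[1], dtype=np.float32)

    def _init_params(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        f = cfg.root_features
        c_in = cfg.in_channels
        for lvl in range(cfg.depth):
            c_out = f * 2**lvl
            self._add(f"wc_down{lvl}_0", (c_out, c_in, 3, 3), c_in * 9, rng)
            self._add(f"wc_down{lvl}_1", (c_out, c_out, 3, 3), c_out * 9, rng)
            c_in = c_out
        for lvl in range(cfg.depth - 2, -1, -1):
            c_hi = f * 2 ** (lvl + 1)
            c_out = f * 2**lvl
            self.params[f"wu_up{lvl}"] = (
                rng.standard_normal((c_hi, c_out, 2, 2)) * np.sqrt(2.0 / (c_hi * 4))
            ).astype(np.float32)
            self.params[f"bu_up{lvl}"] = np.zeros(c_out, dtype=np.float32)
            self._add(f"wc_up{lvl}_0", (c_out, 2 * c_out, 3, 3), 2 * c_out * 9, rng)
            self._add(f"wc_up{lvl}_1", (c_out, c_out, 3, 3), c_out * 9, rng)
        self.params["wo_final"] = (
            rng.standard_normal((cfg.n_classes, f)) * np.sqrt(2.0 / f)
        ).astype(np.float32)
        self.params["bo_final"] = np.zeros(cfg.n_classes, dtype=np.float32)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------------

    def _divisor(self) -> int:
        return 2 ** (self.config.depth - 1)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a batch (N, C, H, W); reflect-pads H, W to the pooling
        divisor and crops back, so the logits match the input raster."""
        cfg = self.config
        n, c, h, w = x.shape
        d = self._divisor()
        if h < 2 or w < 2:
            raise ValueError(f"input {h}x{w} too small for depth {cfg.depth}")
        ph, pw = (-h) % d, (-w) % d
        xf = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="symmetric").astype(np.float32)
        p = self.params
        cache = {"x": x, "pad": (ph, pw)}
        cur = xf
        for lvl in range(cfg.depth):
            for k in (0, 1):
                name = f"down{lvl}_{k}"
                cache[f"in_{name}"] = cur
                cur = _conv3(cur, p[f"wc_{name}"], p[f"bc_{name}"])
                cache[f"relu_{name}"] = cur > 0
                cur = np.maximum(cur, 0.0)
            if lvl < cfg.depth - 1:
                cache[f"skip{lvl}"] = cur
                cur, cache[f"pool{lvl}"] = _maxpool2(cur)
        for lvl in range(cfg.depth - 2, -1, -1):
            cache[f"in_up{lvl}"] = cur
            cur = _upconv2(cur, p[f"wu_up{lvl}"], p[f"bu_up{lvl}"])
            cur = np.concatenate([cache[f"skip{lvl}"], cur], axis=1)
            for k in (0, 1):
                name = f"up{lvl}_{k}"
                cache[f"in_{name}"] = cur
                cur = _conv3(cur, p[f"wc_{name}"], p[f"bc_{name}"])
                cache[f"relu_{name}"] = cur > 0
                cur = np.maximum(cur, 0.0)
        cache["in_final"] = cur
        logits_full = _conv1(cur, p["wo_final"], p["bo_final"])
        logits = logits_full[:, :, :h, :w]
        if want_cache:
            cache["full_shape"] = logits_full.shape
            return logits, cache
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        cfg = self.config
        p = self.params
        grads = {}
        full = np.zeros(cache["full_shape"], dtype=np.float32)
        full[:, :, : dlogits.shape[2], : dlogits.shape[3]] = dlogits
        dcur, grads["wo_final"], grads["bo_final"] = _conv1_backward(
            cache["in_final"], p["wo_final"], full
        )
        for lvl in range(0, cfg.depth - 1):
            for k in (1, 0):
                name = f"up{lvl}_{k}"
                dcur = dcur * cache[f"relu_{name}"]
                dcur, grads[f"wc_{name}"], grads[f"bc_{name}"] = _conv3_backward(
                    cache[f"in_{name}"], p[f"wc_{name}"], dcur
                )
            c_skip = cache[f"skip{lvl}"].shape[1]
            dskip, dup = dcur[:, :c_skip], dcur[:, c_skip:]
            dcur, grads[f"wu_up{lvl}"], grads[f"bu_up{lvl}"] = _upconv2_backward(
                cache[f"in_up{lvl}"], p[f"wu_up{lvl}"], dup
            )
            # gradient also flows into the skip branch of the encoder
            cache[f"dskip{lvl}"] = dskip
        for lvl in range(cfg.depth - 1, -1, -1):
            if lvl < cfg.depth - 1:
                dcur = _maxpool2_backward(cache[f"pool{lvl}"], dcur)
                dcur = dcur + cache[f"dskip{lvl}"]
            for k in (1, 0):
                name = f"down{lvl}_{k}"
                dcur = dcur * cache[f"relu_{name}"]
                dcur, grads[f"wc_{name}"], grads[f"bc_{name}"] = _conv3_backward(
                    cache[f"in_{name}"], p[f"wc_{name}"], dcur
                )
        return grads

    # -- optimization -------------------------------------------------------

    def adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m.get(k)
            if m is None:
                m = np.zeros_like(self.params[k])
                self._adam_m[k] = m
                self._adam_v[k] = np.zeros_like(self.params[k])
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str) -> "UNet":
        data = np.load(path)
        meta = json.loads(bytes(data["__config__"]).decode())
        model = cls(UNetConfig(**meta))
        for k in model.params:
            model.params[k] = data[k].astype(np.float32)
        return model


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    pixel_accuracy: list = field(default_factory=list)


def build_model(config: UNetConfig) -> UNet:
    """Construct the network with seeded (hence reproducible) initialization."""
    return UNet(config)


def train(model: UNet, patches: PatchSet, config: UNetConfig | None = None) -> TrainingHistory:
    """Adam on pixel-wise cross-entropy over seeded shuffled mini-batches.

    Runs ``epochs`` epochs of ``iterations_per_epoch`` steps and records the
    mean loss and pixel accuracy of each epoch.
    """
    cfg = config or model.config
    if len(patches) == 0:
        raise ValueError("cannot train on an empty PatchSet")
    x, y = patches.arrays()
    x = x[:, None, :, :]  # (N, 1, H, W)
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(len(x))
    pos = 0
    history = TrainingHistory()
    for _ in range(cfg.epochs):
        losses = []
        accs = []
        for _ in range(cfg.iterations_per_epoch):
            if pos + cfg.batch_size > len(order):
                order = rng.permutation(len(x))
                pos = 0
            idx = order[pos : pos + cfg.batch_size]
            pos += cfg.batch_size
            logits, cache = model.forward(x[idx], want_cache=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; aborting")
            grads = model.backward(cache, dlogits)
            model.adam_step(grads, cfg.learning_rate)
            losses.append(loss)
            accs.append(float((logits.argmax(axis=1) == y[idx]).mean()))
        history.loss.append(float(np.mean(losses)))
        history.pixel_accuracy.append(float(np.mean(accs)))
    return history


def predict_probability_map(model: UNet, img: GrayImage) -> ProbabilityMap:
    """Border-class softmax probability per pixel (class 1 = border)."""
    x = img.pixels.astype(np.float32)[None, None]
    logits = model.forward(x)
    probs = _softmax(logits.astype(np.float64))[0, 1]
    return ProbabilityMap(np.clip(probs, 0.0, 1.0), image_id=img.id)
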