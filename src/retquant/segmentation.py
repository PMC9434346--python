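"""Fully convolutional multi-class segmentation of IRF, SRF, SHRM and PED.

A small U-shaped encoder-decoder (configurable depth/width, softmax head,
pixelwise cross-entropy) replaces the large pretrained backbone: acceptance
runs must work offline on one CPU. Labels are mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .synthetic import BScanImage, LABEL_CODES, LESION_CLASSES

logger = logging.getLogger(__name__)

N_CLASSES = 5


@dataclass
class LesionSegmentation:
    labels: np.ndarray          # (H, W) uint8 in {0..4}
    probabilities: np.ndarray   # (5, H, W), sums to 1 per pixel


@dataclass
class FcnConfig:
    channels: tuple[int, ...] = (8, 16, 32)   # encoder widths, last = bottleneck
    n_classes: int = N_CLASSES
    kernel: int = 3
    learning_rate: float = 0.05
    momentum: float = 0.9
    epochs: int = 15
    batch_size: int = 2
    seed: int = 0
    pretrained: bool = False     # kept for interface parity; no weights shipped
    class_weighting: bool = True

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs={self.epochs} must be >= 1")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must be {N_CLASSES}")
        if len(self.channels) < 2:
            raise ValueError("need at least two resolution levels")


class _UNet(nn.Layer):
    """U-shaped encoder-decoder with nearest-neighbour upsampling and
    concatenated skip connections; one conv block per level."""

    def __init__(self, config: FcnConfig, rng: np.random.Generator):
        ch = config.channels
        k = config.kernel
        blk = lambda ci, co: nn.Sequential(nn.Conv2d(ci, co, k, rng=rng),
                                           nn.BatchNorm2d(co), nn.ReLU())
        self.depth = len(ch) - 1
        self.enc = [blk(1 if i == 0 else ch[i - 1], ch[i])
                    for i in range(self.depth)]
        self.bottleneck = blk(ch[-2], ch[-1])
        self.dec = [blk(ch[i + 1] + ch[i], ch[i])
                    for i in reversed(range(self.depth))]
        self.head = nn.Conv2d(ch[0], config.n_classes, 1, rng=rng)
        self.pool = nn.MaxPool2d()
        self.up = nn.UpsampleNearest2d()
        self._all = nn.Sequential(*self.enc, self.bottleneck, *self.dec,
                                  self.head)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pools, self._skips = [], []
        for enc in self.enc:
            x = enc.forward(x)
            self._skips.append(x)
            pool = nn.MaxPool2d()
            x = pool.forward(x)
            self._pools.append(pool)
        x = self.bottleneck.forward(x)
        self._cat_ch = []
        for dec, skip in zip(self.dec, reversed(self._skips)):
            x = self.up.forward(x)
            self._cat_ch.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        skip_grads = []
        for dec, cat_ch in zip(self.dec[::-1], self._cat_ch[::-1]):
            g = dec.backward(grad)
            g_up, g_skip = g[:, :cat_ch], g[:, cat_ch:]
            skip_grads.append(g_skip)
            grad = self.up.backward(g_up)
        grad = self.bottleneck.backward(grad)
        for enc, pool, g_skip in zip(self.enc[::-1], self._pools[::-1],
                                     skip_grads[::-1]):
            grad = pool.backward(grad) + g_skip
            grad = enc.backward(grad)
        self._pools = self._skips = None
        return grad

    def parameters(self) -> list[dict]:
        return self._all.parameters()

    def train(self) -> None:
        self._all.train()

    def eval(self) -> None:
        self._all.eval()


def _weighted_ce(logits: np.ndarray, labels: np.ndarray,
                 class_w: np.ndarray) -> tuple[float, np.ndarray]:
    p = nn.softmax(logits, axis=1)
    wpix = class_w[labels].astype(np.float32)         # (N, H, W)
    wsum = float(wpix.sum())
    picked = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    loss = float(-(wpix * np.log(np.clip(picked, 1e-12, None))).sum() / wsum)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    grad = (p - onehot) * wpix[:, None] / wsum
    return loss, grad.astype(np.float32)


@dataclass
class FcnModel:
    net: _UNet
    config: FcnConfig
    class_weights: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def save(self, path: str) -> None:
        meta = {"cfg_channels": np.asarray(self.config.channels),
                "cfg_kernel": self.config.kernel,
                "cfg_seed": self.config.seed,
                "class_weights": self.class_weights}
        np.savez(path, **meta, **nn.state_dict(self.net._all))

    @classmethod
    def load(cls, path: str) -> "FcnModel":
        data = np.load(path, allow_pickle=False)
        config = FcnConfig(channels=tuple(int(c) for c in data["cfg_channels"]),
                           kernel=int(data["cfg_kernel"]),
                           seed=int(data["cfg_seed"]))
        net = _UNet(config, np.random.default_rng(0))
        nn.load_state_dict(net._all, {k: data[k] for k in data.files
                                      if not k.startswith("cfg_")
                                      and k != "class_weights"})
        return cls(net=net, config=config,
                   class_weights=data["class_weights"])


def _check_geometry(shape: tuple[int, int], depth: int) -> None:
    h, w = shape
    f = 2 ** depth
    if h % f or w % f:
        raise ValueError(
            f"image {h}x{w} not divisible by 2^depth={f}; crop first")


def train_fcn(train_set: list[tuple[BScanImage, np.ndarray]],
              config: FcnConfig | None = None) -> FcnModel:
    """Train the segmentation network on (image, label-mask) pairs."""
    config = config or FcnConfig()
    config.validate()
    if not train_set:
        raise ValueError("empty training set")
    masks = np.stack([np.asarray(m) for _i, m in train_set]).astype(np.int64)
    present = {cls for cls in LESION_CLASSES
               if (masks == LABEL_CODES[cls]).any()}
    absent = [cls for cls in LESION_CLASSES if cls not in present]
    if absent:
        raise ValueError(f"training set missing lesion classes: {absent}")
    x = np.stack([img.intensity for img, _m in train_set]
                 ).astype(np.float32)[:, None]
    _check_geometry(x.shape[2:], len(config.channels) - 1)

    if config.class_weighting:
        counts = np.bincount(masks.ravel(), minlength=N_CLASSES).astype(float)
        w = counts.sum() / np.maximum(counts, 1.0) / N_CLASSES
        class_w = np.clip(w, 0.1, 50.0)
    else:
        class_w = np.ones(N_CLASSES)

    rng = np.random.default_rng(config.seed)
    net = _UNet(config, rng)
    opt = nn.SGD(net.parameters(), lr=config.learning_rate,
                 momentum=config.momentum)
    model = FcnModel(net=net, config=config, class_weights=class_w)

    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        net.train()
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = net.forward(x[idx])
            loss, grad = _weighted_ce(logits, masks[idx], class_w)
            net.backward(grad)
            opt.step()
            total += loss * idx.size
        model.loss_history.append(total / n)
        logger.info("fcn epoch %d loss %.4f", epoch, total / n)
    return model


def segment(model: FcnModel, img: BScanImage | np.ndarray
            ) -> LesionSegmentation:
    """Argmax label map; deterministic given weights and input."""
    data = img.intensity if isinstance(img, BScanImage) else np.asarray(img)
    data = data.astype(np.float32)
    _check_geometry(data.shape, len(model.config.channels) - 1)
    model.net.eval()
    logits = model.net.forward(data[None, None])
    probs = nn.softmax(logits, axis=1)[0]
    return LesionSegmentation(labels=probs.argmax(axis=0).astype(np.uint8),
                              probabilities=probs)
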