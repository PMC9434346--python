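"""Clip-based detection of EZ/ELM presence.

An image is sliced into vertical 16-px-wide clips; a small CNN (four blocks
of conv + batch norm + ReLU + max-pool, then two fully connected layers,
binary cross-entropy) classifies each clip, and per-clip decisions are
merged back into a per-image presence vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .synthetic import AnnotationSet, BScanImage, CLIP_WIDTH

logger = logging.getLogger(__name__)

LAYERS = ("ez", "elm")


@dataclass
class ClipGrid:
    clips: np.ndarray              # (n_clips, H, 16), left to right
    clip_width: int = CLIP_WIDTH

    @property
    def n_clips(self) -> int:
        return self.clips.shape[0]

    def concatenate(self) -> np.ndarray:
        """Reassemble the original image bit-exactly."""
        return np.concatenate(list(self.clips), axis=1)


@dataclass
class LayerDetectionResult:
    probabilities: np.ndarray      # (n_clips,) in [0, 1]
    presence: np.ndarray           # (n_clips,) bool, prob >= threshold
    threshold: float


@dataclass
class ClipCnnConfig:
    n_blocks: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    fc_width: int = 64
    learning_rate: float = 0.02
    momentum: float = 0.9
    epochs: int = 20
    batch_size: int = 32
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks != len(self.channels):
            raise ValueError("channels must list one width per block")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold={self.threshold} outside (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def slice_clips(img: BScanImage | np.ndarray) -> ClipGrid:
    """Slice into contiguous, non-overlapping H x 16 clips."""
    data = img.intensity if isinstance(img, BScanImage) else np.asarray(img)
    h, w = data.shape
    if w % CLIP_WIDTH != 0:
        raise ValueError(
            f"width {w} not divisible by {CLIP_WIDTH}; re-crop the image")
    n = w // CLIP_WIDTH
    clips = data.reshape(h, n, CLIP_WIDTH).transpose(1, 0, 2)
    return ClipGrid(clips=np.ascontiguousarray(clips))


def clip_label(annotation: AnnotationSet, layer: str, clip_index: int) -> bool:
    """True iff the layer's trace is present in >=1 column of the clip."""
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    trace = annotation.ez_trace if layer == "ez" else annotation.elm_trace
    n_clips = trace.size // CLIP_WIDTH
    if not 0 <= clip_index < n_clips:
        raise IndexError(f"clip_index {clip_index} out of range [0, {n_clips})")
    cols = trace[clip_index * CLIP_WIDTH:(clip_index + 1) * CLIP_WIDTH]
    return bool(np.any(~np.isnan(cols)))


def clip_labels(annotation: AnnotationSet, layer: str) -> np.ndarray:
    n = (annotation.ez_trace.size // CLIP_WIDTH)
    return np.array([clip_label(annotation, layer, i) for i in range(n)])


def _build_net(config: ClipCnnConfig, input_h: int,
               rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    in_ch = 1
    for ch in config.channels:
        layers += [nn.Conv2d(in_ch, ch, config.kernel, rng=rng),
                   nn.BatchNorm2d(ch), nn.ReLU(), nn.MaxPool2d()]
        in_ch = ch
    flat = in_ch * (input_h // 2 ** config.n_blocks) \
        * max(1, CLIP_WIDTH // 2 ** config.n_blocks)
    layers += [nn.Flatten(), nn.Linear(flat, config.fc_width, rng=rng),
               nn.ReLU(), nn.Linear(config.fc_width, 1, rng=rng)]
    return nn.Sequential(*layers)


@dataclass
class ClipCnnModel:
    """Trained clip classifier handle."""

    net: nn.Sequential
    config: ClipCnnConfig
    input_height: int
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, clips: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        self.net.eval()
        x = np.asarray(clips, dtype=np.float32)[:, None, :, :]
        out = [nn.sigmoid(self.net.forward(x[i:i + batch_size]))[:, 0]
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out)

    def save(self, path: str) -> None:
        state = nn.state_dict(self.net)
        meta = {f"cfg_{k}": np.asarray(v)
                for k, v in vars(self.config).items()}
        np.savez(path, input_height=self.input_height, **meta, **state)

    @classmethod
    def load(cls, path: str) -> "ClipCnnModel":
        data = np.load(path, allow_pickle=False)
        cfg_kw = {}
        for k in data.files:
            if k.startswith("cfg_"):
                v = data[k]
                name = k[4:]
                if name == "channels":
                    cfg_kw[name] = tuple(int(c) for c in v)
                elif v.dtype.kind in "iu":
                    cfg_kw[name] = int(v)
                else:
                    cfg_kw[name] = float(v)
        config = ClipCnnConfig(**cfg_kw)
        input_h = int(data["input_height"])
        net = _build_net(config, input_h, np.random.default_rng(0))
        nn.load_state_dict(net, {k: data[k] for k in data.files
                                 if not k.startswith("cfg_")
                                 and k != "input_height"})
        return cls(net=net, config=config, input_height=input_h)


def train_clip_cnn(train_set: list[tuple[np.ndarray, bool]],
                   config: ClipCnnConfig | None = None) -> ClipCnnModel:
    """Train one binary clip classifier (one independent model per layer)."""
    config = config or ClipCnnConfig()
    config.validate()
    if not train_set:
        raise ValueError("empty training set")
    labels = np.array([bool(lbl) for _c, lbl in train_set])
    if labels.all() or not labels.any():
        raise ValueError("training set must contain both labels")
    x = np.stack([np.asarray(c, dtype=np.float32) for c, _l in train_set])
    if x.shape[2] != CLIP_WIDTH:
        raise ValueError(f"clips must be H x {CLIP_WIDTH}")
    y = labels.astype(np.float32)

    rng = np.random.default_rng(config.seed)
    net = _build_net(config, x.shape[1], rng)
    opt = nn.SGD(net.parameters(), lr=config.learning_rate,
                 momentum=config.momentum)
    model = ClipCnnModel(net=net, config=config, input_height=x.shape[1])

    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        net.train()
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x[idx][:, None, :, :]
            opt.zero_grad()
            logits = net.forward(xb)
            loss, grad = nn.bce_with_logits(logits[:, 0], y[idx])
            net.backward(grad[:, None])
            opt.step()
            total += loss * idx.size
        model.loss_history.append(total / n)
        logger.debug("clip-cnn epoch %d loss %.4f", epoch, total / n)
    return model


def detect_layers(model: ClipCnnModel, img: BScanImage | np.ndarray,
                  threshold: float | None = None) -> LayerDetectionResult:
    """Clip, predict per clip, and merge into a per-image presence vector."""
    grid = slice_clips(img)
    thr = model.config.threshold if threshold is None else threshold
    probs = model.predict_proba(grid.clips)
    return LayerDetectionResult(probabilities=probs,
                                presence=probs >= thr, threshold=thr)
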