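"""Minimal numpy neural-network engine (conv/BN/ReLU/pool/linear, SGD).

Small, CPU-only replacement for a deep-learning framework: just the layers
needed by the clip classifier and the segmentation network, with manual
backprop. All tensors are float32, NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "UpsampleNearest2d",
    "Flatten",
    "Linear",
    "Sequential",
    "SGD",
    "bce_with_logits",
    "softmax_cross_entropy",
    "softmax",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base layer: forward caches what backward needs."""

    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        return []

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) padded input -> (N*H'*W', C*k*k) patch matrix, stride 1."""
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, OH, OW, k, k) -> (N, OH, OW, C, k, k)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(col)


class Conv2d(Layer):
    """Stride-1 'same' convolution (odd kernel), He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((out_ch, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        self._shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._col = _im2col(xp, self.k)
        n, _, h, w = x.shape
        out = self._col @ self.w.T + self.b
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.dw += g.T @ self._col
        self.db += g.sum(axis=0)
        # dx = 'same' conv of grad with spatially-flipped, channel-swapped W
        wf = self.w.reshape(self.out_ch, self.in_ch, self.k, self.k)
        wf = wf[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.in_ch, self.out_ch * self.k * self.k)
        p = self.k // 2
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gcol = _im2col(gp, self.k)
        dx = (gcol @ wf.T).reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)
        self._col = None
        return dx

    def parameters(self) -> list[dict]:
        return [{"value": self.w, "grad": self.dw, "name": "w"},
                {"value": self.b, "grad": self.db, "name": "b"}]


class BatchNorm2d(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        istd = 1.0 / np.sqrt(var + self.eps)
        self._istd = istd.astype(np.float32)
        self._xhat = ((x - m) * istd[None, :, None, None]).astype(np.float32)
        return self.gamma[None, :, None, None] * self._xhat \
            + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        m = n * h * w
        self.dgamma += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        gs = g.sum(axis=(0, 2, 3), keepdims=True)
        gxs = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - gs / m - self._xhat * gxs / m) \
            * self._istd[None, :, None, None]
        self._xhat = None
        return dx.astype(np.float32)

    def parameters(self) -> list[dict]:
        return [{"value": self.gamma, "grad": self.dgamma, "name": "gamma"},
                {"value": self.beta, "grad": self.dbeta, "name": "beta"}]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, grad, 0.0).astype(np.float32)
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2. H and W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._arg = None
        return out.reshape(n, c, h, w)


class UpsampleNearest2d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_f)
        self.w = (rng.standard_normal((out_f, in_f)) * scale).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw += grad.T @ self._x
        self.db += grad.sum(axis=0)
        dx = grad @ self.w
        self._x = None
        return dx

    def parameters(self) -> list[dict]:
        return [{"value": self.w, "grad": self.dw, "name": "w"},
                {"value": self.b, "grad": self.db, "name": "b"}]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad

    def parameters(self) -> list[dict]:
        return [p for lyr in self.layers for p in lyr.parameters()]

    def train(self) -> None:
        for lyr in self.layers:
            lyr.train()

    def eval(self) -> None:
        for lyr in self.layers:
            lyr.eval()


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[dict], lr: float = 0.05,
                 momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self._vel = [np.zeros_like(p["value"]) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p["grad"][...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * p["grad"]
            p["value"] += v


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    z, y = logits.astype(np.float64), targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss.mean()), grad.astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Pixelwise CE: logits (N,K,H,W), integer labels (N,H,W)."""
    p = softmax(logits, axis=1)
    n, k, h, w = logits.shape
    idx = (np.arange(n)[:, None, None], labels,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    picked = np.take_along_axis(p, labels[:, None, :, :], axis=1)[:, 0]
    loss = -np.log(np.clip(picked, 1e-12, None)).mean()
    grad = p.copy()
    onehot_idx = (np.arange(n)[:, None, None], labels,
                  np.broadcast_to(np.arange(h)[None, :, None], labels.shape),
                  np.broadcast_to(np.arange(w)[None, None, :], labels.shape))
    grad[onehot_idx] -= 1.0
    grad /= n * h * w
    del idx
    return float(loss), grad.astype(np.float32)


def state_dict(net: Layer) -> dict[str, np.ndarray]:
    """Flatten all learnable tensors plus batch-norm running stats."""
    state: dict[str, np.ndarray] = {}

    def visit(layer: Layer, prefix: str) -> None:
        if isinstance(layer, Sequential):
            for i, sub in enumerate(layer.layers):
                visit(sub, f"{prefix}{i}.")
            return
        for p in layer.parameters():
            state[f"{prefix}{p['name']}"] = p["value"]
        if isinstance(layer, BatchNorm2d):
            state[f"{prefix}running_mean"] = layer.running_mean
            state[f"{prefix}running_var"] = layer.running_var

    visit(net, "")
    return state


def load_state_dict(net: Layer, state: dict[str, np.ndarray]) -> None:
    def visit(layer: Layer, prefix: str) -> None:
        if isinstance(layer, Sequential):
            for i, sub in enumerate(layer.layers):
                visit(sub, f"{prefix}{i}.")
            return
        for p in layer.parameters():
            p["value"][...] = state[f"{prefix}{p['name']}"]
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = state[f"{prefix}running_mean"]
            layer.running_var[...] = state[f"{prefix}running_var"]

    visit(net, "")
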