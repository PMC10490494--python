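"""Minimal NumPy layer engine with explicit backpropagation.

Tensors are float32 NCHW. Each layer implements ``forward(x, train)``
(caching whatever backward needs) and ``backward(dy)`` (returning the
input gradient and filling ``self.grads``). Trainable arrays live in
``self.params``; gradients accumulate into same-shaped arrays in
``self.grads``. Scope is exactly what the segmentation architectures
need: stride-1 'same' convolutions, batch normalization, ReLU/sigmoid,
2x2 max pooling, 2x2-stride-2 transposed convolution, and dense layers.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError


class Layer:
    """Base class: stateless unless a subclass declares params."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    # non-trainable buffers (e.g. batch-norm running stats) for checkpoints
    def buffers(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    """3x3/5x5/7x7/1x1 'same' convolution, stride 1, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValidationError("Conv2d requires an odd kernel for 'same' padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.params["W"] = rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    @staticmethod
    def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
        """(B,C,H,W) -> (B*H*W, C*k*k) patch matrix of the padded input."""
        b, c, h, w = x.shape
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k) -> matrix
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * h * w, c * k * k
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValidationError(f"Conv2d expected {self.in_ch} channels, got {c}")
        cols = self._im2col(x, self.k, self.pad)
        y = cols @ self.params["W"].reshape(self.out_ch, -1).T + self.params["b"]
        if train:
            self._cols, self._in_shape = cols, x.shape
        return y.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = self._in_shape
        dy_m = dy.transpose(0, 2, 3, 1).reshape(b * h * w, self.out_ch)
        self.grads["W"] += (dy_m.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] += dy_m.sum(axis=0)
        # dx = 'full' correlation of dy with the flipped, transposed kernel
        w_flip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,k,k)
        cols_dy = self._im2col(dy, self.k, self.k - 1 - self.pad)
        dx = cols_dy @ w_flip.reshape(self.in_ch, -1).T
        self._cols = None
        return dx.reshape(b, h, w, self.in_ch).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        dxhat = dy * self.params["gamma"][None, :, None, None]
        # per-channel sums, kept broadcastable
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (inv_std[None, :, None, None] / n) * (
            n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first window element."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValidationError("MaxPool2d needs even spatial dims")
        win = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        if train:
            self._idx, self._in_shape = idx, x.shape
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        flat = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        win = flat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return win.reshape(b, c, h, w)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        std = np.sqrt(2.0 / (in_ch * 4))
        self.params["W"] = rng.normal(0.0, std, (in_ch, out_ch, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if train:
            self._x = x
        y = np.einsum("bchw,coij->bohiwj", x, self.params["W"], optimize=True)
        y = y.reshape(b, self.out_ch, 2 * h, 2 * w)
        return (y + self.params["b"][None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, o, h2, w2 = dy.shape
        dyr = dy.reshape(b, o, h2 // 2, 2, w2 // 2, 2)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        self.grads["W"] += np.einsum("bchw,bohiwj->coij", self._x, dyr, optimize=True)
        dx = np.einsum("bohiwj,coij->bchw", dyr, self.params["W"], optimize=True)
        self._x = None
        return dx.astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, std, (in_features, out_features)).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Flatten(Layer):
    """(B, C, H, W) -> (B, C*H*W)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    """(B, F) -> (B, *shape)."""

    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(dy.shape[0], -1)


class Sequential(Layer):
    """Chain of layers; backward runs in reverse."""

    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def iter_layers(root: Layer):
    """Yield leaf layers of a layer tree (Sequential containers expanded)."""
    if isinstance(root, Sequential):
        for child in root.layers:
            yield from iter_layers(child)
    else:
        yield root
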