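"""Layers with explicit forward/backward passes.

Conventions: 1-D feature maps are (N, C, L), 2-D maps are (N, C, H, W), flat
features are (N, F). Convolutions are stride-1 with 'same' zero padding (odd
kernels); spatial downsampling is done by max pooling. Trainable arrays live
in ``layer.params`` with matching gradients in ``layer.grads``; non-trainable
state (batch-norm running moments) lives in ``layer.buffers``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigError


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.training = True
        self.sublayers: list[Layer] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def iter_layers(layer: Layer):
    """Depth-first traversal over a layer tree (the layer itself included)."""
    yield layer
    for sub in layer.sublayers:
        yield from iter_layers(sub)


def set_training(layer: Layer, flag: bool) -> None:
    for sub in iter_layers(layer):
        sub.training = flag


def state_dict(net: Layer) -> dict[str, np.ndarray]:
    out = {}
    for i, layer in enumerate(iter_layers(net)):
        for name, arr in {**layer.params, **layer.buffers}.items():
            out[f"{i}.{name}"] = arr.copy()
    return out


def load_state_dict(net: Layer, sd: dict[str, np.ndarray]) -> None:
    for i, layer in enumerate(iter_layers(net)):
        for name in layer.params:
            layer.params[name][...] = sd[f"{i}.{name}"]
        for name in layer.buffers:
            layer.buffers[name][...] = sd[f"{i}.{name}"]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.sublayers = list(layers)

    def forward(self, x):
        for layer in self.sublayers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.sublayers):
            dy = layer.backward(dy)
        return dy


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv1d(Layer):
    """Stride-1 'same'-padded 1-D convolution over (N, C, L) feature maps."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ConfigError("Conv1d kernel must be odd for 'same' padding")
        self.k = kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel
        self.params["W"] = rng.standard_normal((c_out, c_in, kernel)) * np.sqrt(
            2.0 / fan_in
        )
        self.params["b"] = np.zeros(c_out)

    def forward(self, x):
        if x.shape[2] < self.k - self.pad:
            raise ConfigError(
                f"signal length {x.shape[2]} too short for kernel {self.k}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp = xp
        win = sliding_window_view(xp, self.k, axis=2)  # (N, C, L, k)
        return (
            np.einsum("nclk,ock->nol", win, self.params["W"], optimize=True)
            + self.params["b"][None, :, None]
        )

    def backward(self, dy):
        win = sliding_window_view(self._xp, self.k, axis=2)
        self.grads["W"] = np.einsum("nclk,nol->ock", win, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2))
        dyp = np.pad(dy, ((0, 0), (0, 0), (self.k - 1, self.k - 1)))
        dwin = sliding_window_view(dyp, self.k, axis=2)  # (N, O, L + k - 1, k)
        wflip = self.params["W"][:, :, ::-1]
        dxp = np.einsum("nomk,ock->ncm", dwin, wflip, optimize=True)
        L = self._xp.shape[2] - 2 * self.pad
        return dxp[:, :, self.pad : self.pad + L]


class Conv2d(Layer):
    """Stride-1 'same'-padded 2-D convolution over (N, C, H, W) feature maps."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ConfigError("Conv2d kernel must be odd for 'same' padding")
        self.k = kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        self.params["W"] = rng.standard_normal(
            (c_out, c_in, kernel, kernel)
        ) * np.sqrt(2.0 / fan_in)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return (
            np.einsum("nchwij,ocij->nohw", win, self.params["W"], optimize=True)
            + self.params["b"][None, :, None, None]
        )

    def backward(self, dy):
        p, k = self.pad, self.k
        win = sliding_window_view(self._xp, (k, k), axis=(2, 3))
        self.grads["W"] = np.einsum("nchwij,nohw->ocij", win, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        dwin = sliding_window_view(dyp, (k, k), axis=(2, 3))
        wflip = self.params["W"][:, :, ::-1, ::-1]
        dxp = np.einsum("nohwij,ocij->nchw", dwin, wflip, optimize=True)
        H = self._xp.shape[2] - 2 * p
        W = self._xp.shape[3] - 2 * p
        return dxp[:, :, p : p + H, p : p + W]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel/feature axis.

    Works on (N, F), (N, C, L) and (N, C, H, W) inputs; the normalized axis is
    1 (or the only feature axis for flat input). Running moments are kept for
    inference.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(num_features)
        self.params["beta"] = np.zeros(num_features)
        self.buffers["running_mean"] = np.zeros(num_features)
        self.buffers["running_var"] = np.ones(num_features)

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        axes = (0,) + tuple(range(2, x.ndim))
        shape = [1] * x.ndim
        shape[1] = -1
        return axes, tuple(shape)

    def forward(self, x):
        axes, shape = self._axes_and_shape(x)
        self._axes, self._shape = axes, shape
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.buffers["running_mean"] *= 1 - self.momentum
            self.buffers["running_mean"] += self.momentum * mean
            self.buffers["running_var"] *= 1 - self.momentum
            self.buffers["running_var"] += self.momentum * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        return self.params["gamma"].reshape(shape) * self._xhat + self.params[
            "beta"
        ].reshape(shape)

    def backward(self, dy):
        axes, shape = self._axes, self._shape
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"].reshape(shape)
        if not self.training:
            return dy * g / self._std.reshape(shape)
        m = dy.size // dy.shape[1]  # batch x spatial elements per channel
        sum_dy = dy.sum(axis=axes).reshape(shape)
        sum_dy_xhat = (dy * self._xhat).sum(axis=axes).reshape(shape)
        return (
            g
            / self._std.reshape(shape)
            / m
            * (m * dy - sum_dy - self._xhat * sum_dy_xhat)
        )


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel = stride = 2) on (N, C, L)."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.k = kernel

    def forward(self, x):
        N, C, L = x.shape
        L2 = L // self.k
        if L2 < 1:
            raise ConfigError(f"signal length {L} too short to max-pool by {self.k}")
        self._in_shape = x.shape
        xr = x[:, :, : L2 * self.k].reshape(N, C, L2, self.k)
        self._amax = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._amax[..., None], axis=3)[..., 0]

    def backward(self, dy):
        N, C, L = self._in_shape
        L2 = L // self.k
        dxr = np.zeros((N, C, L2, self.k))
        np.put_along_axis(dxr, self._amax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, : L2 * self.k] = dxr.reshape(N, C, L2 * self.k)
        return dx


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling on (N, C, H, W)."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.k = kernel

    def forward(self, x):
        k = self.k
        N, C, H, W = x.shape
        H2, W2 = H // k, W // k
        if H2 < 1 or W2 < 1:
            raise ConfigError(f"feature map {H}x{W} too small to pool by {k}")
        self._in_shape = x.shape
        xr = (
            x[:, :, : H2 * k, : W2 * k]
            .reshape(N, C, H2, k, W2, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H2, W2, k * k)
        )
        self._amax = xr.argmax(axis=4)
        return np.take_along_axis(xr, self._amax[..., None], axis=4)[..., 0]

    def backward(self, dy):
        k = self.k
        N, C, H, W = self._in_shape
        H2, W2 = H // k, W // k
        dxr = np.zeros((N, C, H2, W2, k * k))
        np.put_along_axis(dxr, self._amax[..., None], dy[..., None], axis=4)
        dx = np.zeros(self._in_shape)
        dx[:, :, : H2 * k, : W2 * k] = (
            dxr.reshape(N, C, H2, W2, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H2 * k, W2 * k)
        )
        return dx


class GlobalAvgPool1d(Layer):
    """Adaptive average pooling to a single position: (N, C, L) -> (N, C)."""

    def forward(self, x):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None] / self._L, self._L, axis=2)


class GlobalAvgPool2d(Layer):
    """Adaptive average pooling to 1x1: (N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        H, W = self._hw
        return np.broadcast_to(
            dy[:, :, None, None] / (H * W), dy.shape + (H, W)
        ).copy()


class _ResBase(Layer):
    """Residual wrapper: relu(main(x) + skip(x)); skip may be identity."""

    def __init__(self, main: Sequential, skip: Sequential | None):
        super().__init__()
        self.main = main
        self.skip = skip
        self.relu = ReLU()
        self.sublayers = [main] + ([skip] if skip is not None else []) + [self.relu]

    def forward(self, x):
        y = self.main.forward(x)
        s = self.skip.forward(x) if self.skip is not None else x
        return self.relu.forward(y + s)

    def backward(self, dy):
        d = self.relu.backward(dy)
        dx = self.main.backward(d)
        if self.skip is not None:
            dx = dx + self.skip.backward(d)
        else:
            dx = dx + d
        return dx


class ConvResBlock2d(_ResBase):
    """Basic 2-conv residual block (3x3, 3x3) with optional 1x1 projection."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel=3):
        main = Sequential(
            [
                Conv2d(c_in, c_out, kernel, rng),
                BatchNorm(c_out),
                ReLU(),
                Conv2d(c_out, c_out, kernel, rng),
                BatchNorm(c_out),
            ]
        )
        skip = (
            None
            if c_in == c_out
            else Sequential([Conv2d(c_in, c_out, 1, rng), BatchNorm(c_out)])
        )
        super().__init__(main, skip)


class Bottleneck2d(_ResBase):
    """Bottleneck residual block (1x1 reduce, 3x3, 1x1 expand), ResNet-50 style."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, rng: np.random.Generator):
        main = Sequential(
            [
                Conv2d(c_in, c_mid, 1, rng),
                BatchNorm(c_mid),
                ReLU(),
                Conv2d(c_mid, c_mid, 3, rng),
                BatchNorm(c_mid),
                ReLU(),
                Conv2d(c_mid, c_out, 1, rng),
                BatchNorm(c_out),
            ]
        )
        skip = (
            None
            if c_in == c_out
            else Sequential([Conv2d(c_in, c_out, 1, rng), BatchNorm(c_out)])
        )
        super().__init__(main, skip)


class DenseResBlock(_ResBase):
    """Residual block on flat features: dense-bn-relu-dense-bn with projection."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        main = Sequential(
            [
                Dense(n_in, n_out, rng),
                BatchNorm(n_out),
                ReLU(),
                Dense(n_out, n_out, rng),
                BatchNorm(n_out),
            ]
        )
        skip = (
            None
            if n_in == n_out
            else Sequential([Dense(n_in, n_out, rng), BatchNorm(n_out)])
        )
        super().__init__(main, skip)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted mean cross-entropy and its gradient w.r.t. the logits."""
    n, k = logits.shape
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[y]
    wsum = w.sum()
    nll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * nll).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits
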