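"""NumPy layers with explicit backward passes.

Tensor convention: (batch, channels, length) for 1-D signals.  Convolutions
use 'same'-style padding: output length ceil(L / stride), with the total pad
split left/right (left gets the smaller half).

The quadratic convolution computes, per output position with x the flattened
receptive-field window,

    out = (x . w_r + b_r) * (x . w_g + b_g) + (x*x) . w_b + c

which reduces exactly to the linear convolution x . w_r + b_r when
w_g = 0, b_g = 1, w_b = 0, c = 0.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def same_padding(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(pad_left, pad_right, out_length) for 'same' 1-D convolution."""
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left, out


def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(N, C, L) -> (N, Lo, C*kernel) window matrix."""
    windows = sliding_window_view(x, kernel, axis=2)[:, :, ::stride, :]
    n, c, lo, k = windows.shape
    return windows.transpose(0, 2, 1, 3).reshape(n, lo, c * k)


def _col2im(dcol: np.ndarray, x_shape: tuple, kernel: int, stride: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add window gradients back to the signal."""
    n, c, L = x_shape
    lo = dcol.shape[1]
    dwin = dcol.reshape(n, lo, c, kernel).transpose(0, 2, 1, 3)  # (N, C, Lo, k)
    dx = np.zeros(x_shape, dtype=dcol.dtype)
    for j in range(kernel):
        dx[:, :, j : j + (lo - 1) * stride + 1 : stride] += dwin[:, :, :, j]
    return dx


class Layer:
    """Minimal layer interface; parameters and their gradients live in dicts."""

    name = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """All persistent arrays (parameters + buffers) for checkpointing."""
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


class _ConvBase(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int):
        super().__init__()
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"{self.name}: expected (N, {self.in_channels}, L), got {x.shape}"
            )
        left, right, _ = same_padding(x.shape[2], self.kernel, self.stride)
        self._pad = (left, right)
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        self._xp_shape = xp.shape
        return _im2col(xp, self.kernel, self.stride)

    def _restore(self, dcol: np.ndarray) -> np.ndarray:
        dxp = _col2im(dcol, self._xp_shape, self.kernel, self.stride)
        left, _ = self._pad
        return dxp[:, :, left : left + self._x_shape[2]]


class Conv1d(_ConvBase):
    """Linear 1-D convolution (cross-correlation) with 'same' padding."""

    name = "conv1d"

    def __init__(self, in_channels, out_channels, kernel, stride, rng: np.random.Generator):
        super().__init__(in_channels, out_channels, kernel, stride)
        fan_in = in_channels * kernel
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in)),
            "b": np.zeros(out_channels),
        }

    def forward(self, x, training=False):
        col = self._prepare(x)
        self._col = col if training else None
        out = col @ self.params["w"].T + self.params["b"]
        return out.transpose(0, 2, 1)

    def backward(self, grad):
        g = grad.transpose(0, 2, 1)  # (N, Lo, O)
        col = self._col
        self.grads["w"] = np.einsum("nlo,nlc->oc", g, col)
        self.grads["b"] = g.sum(axis=(0, 1))
        return self._restore(g @ self.params["w"])


class QuadConv1d(_ConvBase):
    """Quadratic 1-D convolution: (x.wr+br)(x.wg+bg) + (x*x).wb + c.

    Initialized to start exactly linear (wg=0, bg=1, wb=0, c=0) so early
    training matches the linear baseline and the reduction property holds at
    initialization.
    """

    name = "quadconv1d"

    def __init__(self, in_channels, out_channels, kernel, stride, rng: np.random.Generator):
        super().__init__(in_channels, out_channels, kernel, stride)
        fan_in = in_channels * kernel
        self.params = {
            "wr": rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in)),
            "br": np.zeros(out_channels),
            "wg": np.zeros((out_channels, fan_in)),
            "bg": np.ones(out_channels),
            "wb": np.zeros((out_channels, fan_in)),
            "c": np.zeros(out_channels),
        }

    def forward(self, x, training=False):
        col = self._prepare(x)
        p = self.params
        u = col @ p["wr"].T + p["br"]
        v = col @ p["wg"].T + p["bg"]
        q = (col * col) @ p["wb"].T + p["c"]
        if training:
            self._col, self._u, self._v = col, u, v
        return (u * v + q).transpose(0, 2, 1)

    def backward(self, grad):
        g = grad.transpose(0, 2, 1)  # (N, Lo, O)
        col, u, v = self._col, self._u, self._v
        du = g * v
        dv = g * u
        p = self.params
        self.grads["wr"] = np.einsum("nlo,nlc->oc", du, col)
        self.grads["br"] = du.sum(axis=(0, 1))
        self.grads["wg"] = np.einsum("nlo,nlc->oc", dv, col)
        self.grads["bg"] = dv.sum(axis=(0, 1))
        self.grads["wb"] = np.einsum("nlo,nlc->oc", g, col * col)
        self.grads["c"] = g.sum(axis=(0, 1))
        dcol = du @ p["wr"] + dv @ p["wg"] + 2.0 * col * (g @ p["wb"])
        return self._restore(dcol)


def quad_conv1d(x: np.ndarray, params: dict[str, np.ndarray], kernel: int, stride: int) -> np.ndarray:
    """Functional quadratic convolution on a (N, C, L) signal.

    ``params`` holds wr, wg, wb of shape (out_channels, in_channels * kernel)
    and br, bg, c of shape (out_channels,).  Activation is NOT applied here;
    it belongs to the layer, not the convolution.
    """
    x = np.asarray(x, dtype=float)
    for key in ("wr", "wg", "wb"):
        if not np.all(np.isfinite(params[key])):
            raise ValueError(f"non-finite weights in {key!r}")
    out_channels, fan_in = params["wr"].shape
    in_channels = x.shape[1]
    if fan_in != in_channels * kernel:
        raise ValueError(
            f"weight fan-in {fan_in} != in_channels*kernel = {in_channels * kernel}"
        )
    layer = QuadConv1d.__new__(QuadConv1d)
    _ConvBase.__init__(layer, in_channels, out_channels, kernel, stride)
    layer.params = params
    return layer.forward(x, training=False)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    name = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        if training:
            self._xhat, self._ivar, self._m = xhat, ivar, x.shape[0] * x.shape[2]
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, grad):
        xhat, ivar, m = self._xhat, self._ivar, self._m
        dgamma = (grad * xhat).sum(axis=(0, 2))
        dbeta = grad.sum(axis=(0, 2))
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        coeff = (self.params["gamma"] * ivar / m)[None, :, None]
        return coeff * (
            m * grad - dbeta[None, :, None] - xhat * dgamma[None, :, None]
        )

    def state(self):
        return {**self.params, "running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        super().load_state(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class ReLU(Layer):
    name = "relu"

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (size == stride, length divisible)."""

    name = "maxpool"

    def __init__(self, size: int = 2):
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def forward(self, x, training=False):
        n, c, L = x.shape
        if L % self.size:
            raise ValueError(f"length {L} not divisible by pool size {self.size}")
        blocks = x.reshape(n, c, L // self.size, self.size)
        if training:
            self._argmax = blocks.argmax(axis=3)
            self._in_shape = x.shape
        return blocks.max(axis=3)

    def backward(self, grad):
        n, c, L = self._in_shape
        dx = np.zeros((n, c, L // self.size, self.size), dtype=grad.dtype)
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=3)
        return dx.reshape(n, c, L)


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    name = "dense"

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features)),
            "b": np.zeros(out_features),
        }

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"]


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    name = "dropout"

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Network:
    """A plain layer sequence with softmax-cross-entropy helpers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, key) for layer in self.layers for key in layer.params]

    def state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.state().items()} for layer in self.layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, s in zip(self.layers, state):
            layer.load_state(s)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits (targets 0-based)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.maximum(p[np.arange(n), targets], 1e-300)).mean())
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n
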