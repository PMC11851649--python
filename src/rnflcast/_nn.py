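"""Minimal 1D convolutional network engine in numpy.

Implements exactly the pieces the RNFL forecasting CNN needs — 1D
convolution with zero 'same' padding, ReLU, width-2 max pooling, fully
connected layers, mean-squared-error loss and the Adam optimizer — with
hand-derived backward passes. Running on numpy keeps training bit-exact
under a fixed seed, which the reproducibility contract relies on.

Shapes follow the (batch, channels, length) convention. Kernel widths must
be odd so 'same' padding is symmetric.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """'Same' (zero-padded) 1D convolution, stride 1, odd kernel width."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd for symmetric same-padding")
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        std = np.sqrt(2.0 / (in_ch * kernel))  # He initialization (ReLU follows)
        self.params = {
            "w": rng.normal(0.0, std, size=(out_ch, in_ch, kernel)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._win = sliding_window_view(xp, self.kernel, axis=2)  # (B, Cin, L, K)
        return np.einsum("bclk,ock->bol", self._win, self.params["w"], optimize=True) \
            + self.params["b"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        self.grads["w"] = np.einsum("bclk,bol->ock", self._win, dy, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2))
        k = self.kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        win2 = sliding_window_view(dyp, k, axis=2)  # (B, Cout, L + K - 1, K)
        wf = w[:, :, ::-1]
        dxp = np.einsum("bomk,ock->bcm", win2, wf, optimize=True)  # (B, Cin, L + 2*pad)
        L = dy.shape[2]
        return dxp[:, :, self.pad:self.pad + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping width-2 max pooling; the length must be even."""

    def __init__(self, width: int = 2):
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, L = x.shape
        if L % self.width:
            raise ValueError(f"length {L} not divisible by pool width {self.width}")
        xr = x.reshape(b, c, L // self.width, self.width)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, L = self._in_shape
        dxr = np.zeros((b, c, L // self.width, self.width))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        return dxr.reshape(b, c, L)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_dim)
        self.params = {
            "w": rng.normal(0.0, std, size=(out_dim, in_dim)),
            "b": np.zeros(out_dim),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": layer.params[name]
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"])


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, net: Sequential, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()} for l in net.layers}
        self.v = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()} for l in net.layers}

    def step(self) -> None:
        self.t += 1
        for layer in self.net.layers:
            for name, p in layer.params.items():
                g = layer.grads[name]
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff


def build_cnn(
    in_channels: int,
    in_length: int,
    out_dim: int,
    conv_channels: tuple[int, ...],
    kernel_sizes: tuple[int, ...],
    fc_sizes: tuple[int, ...],
    rng: np.random.Generator,
    pool_width: int = 2,
) -> Sequential:
    """Conv(→ReLU→pool) blocks followed by ReLU-separated FC layers and a linear head."""
    if len(conv_channels) != len(kernel_sizes):
        raise ValueError("conv_channels and kernel_sizes must have equal length")
    layers: list[Layer] = []
    ch, length = in_channels, in_length
    for out_ch, k in zip(conv_channels, kernel_sizes):
        layers += [Conv1d(ch, out_ch, k, rng), ReLU(), MaxPool1d(pool_width)]
        ch, length = out_ch, length // pool_width
    layers.append(Flatten())
    dim = ch * length
    for fc in fc_sizes:
        layers += [Linear(dim, fc, rng), ReLU()]
        dim = fc
    layers.append(Linear(dim, out_dim, rng))
    return Sequential(layers)
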