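"""Small CPU-only neural-network core (NumPy).

Just enough machinery for tiny patch classifiers: same-padded square
convolutions via im2col + BLAS matmul, max-downsampling, dense layers with
ReLU, a softmax/cross-entropy head and SGD with momentum.  Everything is
seeded and deterministic.

Activations are laid out NHWC — ``(batch, height, width, channels)`` — so
im2col is a single reshape of a sliding-window view and forward/backward
reduce to one large matrix product each.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, C*k*k) patch matrix for a same-padded conv.

    Column order is (channel, kernel row, kernel col), matching the weight
    layout below.
    """
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # windows over the spatial axes: (N, H, W, C, k, k)
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    return win.reshape(n * h * w, c * k * k)


class Conv2D(Layer):
    """Same-padded square convolution; weights stored as (C*k*k, F).

    The backward-data pass is the transposed convolution — a same-padded
    convolution of the output gradient with spatially flipped,
    channel-transposed weights — so no scatter-add is ever needed.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        self.cin, self.f, self.k = in_channels, filters, kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        self._in_shape = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.f)

    def _flipped_weights(self) -> np.ndarray:
        # (F*k*k, C): Wt[(f, u, v), c] = W[(c, k-1-u, k-1-v), f]
        w4 = self.W.reshape(self.cin, self.k, self.k, self.f)
        return np.ascontiguousarray(
            w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.f * self.k * self.k, self.cin)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dflat = dout.reshape(n * h * w, self.f)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dout_cols = _im2col(dout, self.k, self.pad)
        dx = dout_cols @ self._flipped_weights()
        return dx.reshape(n, h, w, c)


class MaxPool2D(Layer):
    """kxk max-downsampling with stride = kernel, floor semantics."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        ho, wo = h // k, w // k
        view = x[:, : ho * k, : wo * k, :].reshape(n, ho, k, wo, k, c)
        out = view.max(axis=(2, 4))
        self._x_shape = x.shape
        self._mask = view == out[:, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        k = self.k
        ho, wo = h // k, w // k
        # distribute to argmax cells; split ties evenly to keep gradients exact
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        dview = self._mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : ho * k, : wo * k, :] = dview.reshape(n, ho * k, wo * k, c)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers for p, g in zip(layer.params, layer.grads)]


class SGDMomentum:
    def __init__(self, network: Network, lr: float, momentum: float = 0.9):
        self.network = network
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in network.parameters()]

    def step(self) -> None:
        for v, (p, g) in zip(self.velocity, self.network.parameters()):
            v *= self.momentum
            v -= self.lr * g
            p += v


def cross_entropy_with_grad(
    probs: np.ndarray, targets: np.ndarray, sample_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and the gradient w.r.t. the logits."""
    n = probs.shape[0]
    w = np.ones(n) if sample_weights is None else sample_weights
    eps = 1e-12
    loss = float(-(w * np.log(probs[np.arange(n), targets] + eps)).sum() / w.sum())
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad
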