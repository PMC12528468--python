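"""Minimal NumPy neural-network engine for the Survpatch regressor.

Implements exactly the pieces the patch regressor needs — 3x3 same-padding
convolution (via column expansion and one matrix multiply per batch),
ReLU, 2x2 max pooling, global average pooling, dense layers, mean
absolute error loss, and Adam — with explicit backpropagation.  Inputs
are (batch, height, width, channels) float32 arrays.

The engine is deliberately small: no autograd, no graph, just layers with
``forward``/``backward`` and a parameter list.  Everything is seeded
through a ``numpy.random.Generator`` so builds and training runs are
reproducible bit-for-bit on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

_DT = np.float32


class Layer:
    """Base layer: parameters and their gradients are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding, He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = 9 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.params = [w.astype(_DT), np.zeros(c_out, dtype=_DT)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        # (B, H, W, C) -> (B, H, W, 9C): the 3x3 neighborhood of every pixel.
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((B, H, W, 9, C), dtype=x.dtype)
        for i, (dy, dx) in enumerate(
            (dy, dx) for dy in (0, 1, 2) for dx in (0, 1, 2)
        ):
            cols[:, :, :, i, :] = xp[:, dy : dy + H, dx : dx + W, :]
        return cols.reshape(B, H, W, 9 * C)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        cols = self._im2col(x)
        if train:
            self._cols = cols
            self._xshape = x.shape
        out = cols.reshape(-1, 9 * C) @ self.params[0] + self.params[1]
        return out.reshape(B, H, W, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, _ = dout.shape
        cols2d = self._cols.reshape(-1, 9 * self.c_in)
        dout2d = dout.reshape(-1, self.c_out)
        self.grads[0][...] = cols2d.T @ dout2d
        self.grads[1][...] = dout2d.sum(axis=0)
        dcols = (dout2d @ self.params[0].T).reshape(B, H, W, 9, self.c_in)
        dxp = np.zeros((B, H + 2, W + 2, self.c_in), dtype=dout.dtype)
        for i, (dy, dx) in enumerate(
            (dy, dx) for dy in (0, 1, 2) for dx in (0, 1, 2)
        ):
            dxp[:, dy : dy + H, dx : dx + W, :] += dcols[:, :, :, i, :]
        self._cols = None
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        xr = (
            x[:, : H2 * 2, : W2 * 2, :]
            .reshape(B, H2, 2, W2, 2, C)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, H2, W2, C, 4)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._inshape = (B, H, W, C)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._inshape
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((B, H2, W2, C, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((B, H, W, C), dtype=dout.dtype)
        dx[:, : H2 * 2, : W2 * 2, :] = (
            dxr.reshape(B, H2, W2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, H2 * 2, W2 * 2, C)
        )
        self._idx = None
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._inshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._inshape
        return np.broadcast_to(dout[:, None, None, :] / (H * W), (B, H, W, C)).astype(
            dout.dtype
        )


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w.astype(_DT), np.zeros(n_out, dtype=_DT)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.params[0].T
        self._x = None
        return dx


class Sequential:
    """An ordered stack of layers with a shared parameter list."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError(f"expected {len(own)} arrays, got {len(weights)}")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adam with the standard moment defaults (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = (np.sign(diff) / diff.size).astype(pred.dtype)
    return loss, grad
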