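"""Minimal numpy neural-network engine for the (6,16,16) tensor
classifier: depth-preserving 3D convolution (kernel depth 1), average
pooling, fully connected layers, ReLU, softmax cross-entropy and Adam.

Layers cache what backpropagation needs on ``forward``; ``backward``
consumes the upstream gradient and fills ``grads`` aligned with
``params``.  Everything is float64 and deterministic given the
initialisation RNG and the batch order.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d1x3x3(Layer):
    """3D convolution with kernel (1,3,3), stride (1,1,1), padding
    (0,1,1): each depth slice is convolved independently with the same
    2D 3x3 filters, mixing channels but never depth planes.

    Input/output layout: ``(N, C, D, H, W)``; H and W are preserved.
    """

    _OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialisation
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x2d: np.ndarray) -> np.ndarray:
        # x2d: (M, C, H, W) -> (M, C*9, H*W), zero padding 1
        M, C, H, W = x2d.shape
        xp = np.zeros((M, C, H + 2, W + 2))
        xp[:, :, 1:-1, 1:-1] = x2d
        cols = np.empty((M, C, 9, H, W))
        for k, (di, dj) in enumerate(self._OFFSETS):
            cols[:, :, k] = xp[:, :, di:di + H, dj:dj + W]
        return cols.reshape(M, C * 9, H * W)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        x2d = x.transpose(0, 2, 1, 3, 4).reshape(N * D, C, H, W)
        cols = self._im2col(x2d)                      # (M, C*9, HW)
        Wmat = self.W.reshape(self.c_out, C * 9)
        out = np.einsum("oc,mcp->mop", Wmat, cols) + self.b[None, :, None]
        self._cache = (cols, (N, C, D, H, W))
        return out.reshape(N, D, self.c_out, H, W).transpose(0, 2, 1, 3, 4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (N, C, D, H, W) = self._cache
        M = N * D
        d2 = dout.transpose(0, 2, 1, 3, 4).reshape(M, self.c_out, H * W)
        Wmat = self.W.reshape(self.c_out, C * 9)
        self.grads[0][...] = np.einsum(
            "mop,mcp->oc", d2, cols).reshape(self.W.shape)
        self.grads[1][...] = d2.sum(axis=(0, 2))
        dcols = np.einsum("oc,mop->mcp", Wmat, d2).reshape(M, C, 9, H, W)
        dxp = np.zeros((M, C, H + 2, W + 2))
        for k, (di, dj) in enumerate(self._OFFSETS):
            dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, k]
        dx2d = dxp[:, :, 1:-1, 1:-1]
        return dx2d.reshape(N, D, C, H, W).transpose(0, 2, 1, 3, 4)


class AvgPool1x2x2(Layer):
    """Average pooling (1,2,2): halves H and W, keeps depth."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        self._shape = x.shape
        return x.reshape(N, C, D, H // 2, 2, W // 2, 2).mean(axis=(4, 6))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, D, H, W = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=3), 2, axis=4) / 4.0
        return d


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


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = dout.T @ self._x
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
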