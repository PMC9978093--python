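"""Minimal seeded feed-forward trainer (dense + 3x3 conv + 2x2 max-pool).

Supports exactly what the two trial classifiers need: He-initialized layers,
ReLU, softmax cross-entropy, minibatch Adam, and deterministic behavior under
a fixed seed.  Float32 throughout; gradients are exact (im2col convolutions).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.W = w.astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv3x3(Layer):
    """Valid 3x3 convolution, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / (c_in * 9))
        self.W = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        n, c, h, w = x.shape
        cols = sliding_window_view(x, (3, 3), axis=(2, 3))  # n,c,h-2,w-2,3,3
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, (h - 2) * (w - 2), c * 9)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.W.reshape(len(self.W), -1).T + self.b
        return out.reshape(n, h - 2, w - 2, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, co, oh, ow = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, oh * ow, co)
        self.grads[0][...] = np.einsum("npk,npc->ck", self._cols, dyf).reshape(self.W.shape)
        self.grads[1][...] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.reshape(co, -1)  # n, oh*ow, c_in*9
        _, c, h, w = self._xshape
        dx = np.zeros(self._xshape, dtype=np.float32)
        dcols = dcols.reshape(n, oh, ow, c, 3, 3)
        for di in range(3):
            for dj in range(3):
                dx[:, :, di : di + oh, dj : dj + ow] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        dflat = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._xshape, dtype=np.float32)
        dblk = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, : 2 * h2, : 2 * w2] = dblk.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for lay in self.layers:
            out = lay.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for lay in reversed(self.layers):
            dy = lay.backward(dy)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """(Optionally class-weighted) mean cross-entropy and its logit gradient.

    ``class_weights[c]`` rescales examples of class c; the loss is normalized
    by the total weight so the gradient scale stays comparable across batches.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights, float)[y]
    total = float(w.sum())
    ce = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * ce).sum() / total)
    dl = p
    dl[np.arange(n), y] -= 1.0
    return loss, (dl * (w / total)[:, None]).astype(np.float32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
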