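"""Minimal NumPy neural-network engine for the fusion regressor.

Implements exactly the pieces the fusion network needs — 1D convolution
(kernel 3, zero-padded 'same') via im2col + BLAS matmul, ReLU, length-2 max
pooling, dropout, a dense layer, and Adam — with hand-written backward
passes.  Activations flow channels-first as (C, B, L) so that im2col and
every gradient reshape are plain contiguous copies or views; all math is
float32.  A single seeded Generator drives weight initialization, shuffling
and dropout, so training histories are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Conv1D:
    """Same-padding (zeros) 1D convolution, kernel length 3, on (C, B, L)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (k * cin))
        self.W = Param(rng.normal(0.0, std, size=(cout, k * cin)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        C, B, L = x.shape
        cols = np.empty((3 * C, B * L), dtype=F32)
        # left-shifted window: first sample position is the zero pad
        left = cols[0:C].reshape(C, B, L)
        left[:, :, 0] = 0.0
        left[:, :, 1:] = x[:, :, :L - 1]
        cols[C:2 * C] = x.reshape(C, B * L)
        right = cols[2 * C:3 * C].reshape(C, B, L)
        right[:, :, :-1] = x[:, :, 1:]
        right[:, :, -1] = 0.0
        y = self.W.value @ cols
        np.add(y, self.b.value[:, None], out=y)
        if train:
            self._cols, self._shape = cols, (C, B, L)
        return y.reshape(self.cout, B, L)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, B, L = self._shape
        g = np.ascontiguousarray(dy).reshape(self.cout, B * L)
        self.W.grad += g @ self._cols.T
        self.b.grad += g.sum(axis=1)
        dcols = self.W.value.T @ g                     # (3C, B*L)
        # dx = center window + shifted left/right windows (zero-pad edges drop)
        dx = dcols[C:2 * C].reshape(C, B, L)
        dx[:, :, :-1] += dcols[0:C].reshape(C, B, L)[:, :, 1:]
        dx[:, :, 1:] += dcols[2 * C:3 * C].reshape(C, B, L)[:, :, :-1]
        self._cols = None
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0, out=x)
        if train:
            self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.multiply(dy, self._mask, out=np.asarray(dy, dtype=F32))
        self._mask = None
        return out


class MaxPool1D:
    """Non-overlapping length-2 max pooling on (C, B, L); odd tail dropped."""

    def __init__(self):
        self._left = None
        self._in_len = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        C, B, L = x.shape
        L2 = L // 2
        a = x[:, :, 0:2 * L2:2]
        b = x[:, :, 1:2 * L2:2]
        y = np.maximum(a, b)
        if train:
            self._left, self._in_len = a >= b, L
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, B, L2 = dy.shape
        dx = np.zeros((C, B, self._in_len), dtype=F32)
        dx[:, :, 0:2 * L2:2] = dy * self._left
        dx[:, :, 1:2 * L2:2] = dy * ~self._left
        self._left = None
        return dx


class DualUnit:
    """Two parallel paths of three chained conv(3)+ReLU layers, summed.

    The first conv of each path maps cin -> cout; the remaining two keep
    cout channels.  This is the dual-channel convolutional unit of the
    absorption branch (12 convolutions per two-unit block).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.paths = []
        for _ in range(2):
            layers = []
            c = cin
            for _ in range(3):
                layers.append(Conv1D(c, cout, rng))
                layers.append(ReLU())
                c = cout
            self.paths.append(layers)

    def params(self):
        return [p for path in self.paths for layer in path for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        outs = []
        for path in self.paths:
            h = x
            for layer in path:
                h = layer.forward(h, train)
            outs.append(h)
        return outs[0] + outs[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        for path in self.paths:
            g = dy.copy()
            for layer in reversed(path):
                g = layer.backward(g)
            dx = g if dx is None else dx + g
        return dx


class Dropout:
    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        if not train or self.p <= 0:
            return x
        keep = rng.random(x.shape, dtype=F32) >= self.p
        self._mask = keep.astype(F32) / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        std = np.sqrt(1.0 / din)
        self.W = Param(rng.normal(0.0, std, size=(dout, din)))
        self.b = Param(np.zeros(dout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value
        self._x = None
        return dx


class Adam:
    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m[...] = b1 * p.m + (1 - b1) * p.grad
            p.v[...] = b2 * p.v + (1 - b2) * p.grad * p.grad
            p.value -= lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)
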