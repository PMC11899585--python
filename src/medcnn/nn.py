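"""Minimal float32 neural-network primitives (1D conv, max-pool, dense)
with reverse-mode gradients and an Adam optimizer.

Implemented directly on NumPy: convolutions are lowered to matrix products
via an im2col sliding-window view, which keeps the training loop
BLAS-bound.  Activations use the channels-last convention (batch, length,
channels) so im2col and pooling never need axis transposes.  Gradient
correctness is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """A differentiable layer; parameters are (array, grad) pairs."""

    def params_and_grads(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution, stride 1, zero 'same' padding, odd kernel size.

    Input (B, L, C_in) -> output (B, L, C_out).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel
        # He-normal init, suited to the ReLU that follows
        self.W = (rng.standard_normal((fan_in, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k, p = self.kernel, self.kernel // 2
        xp = np.zeros((B, L + 2 * p, C), dtype=DTYPE)
        xp[:, p:p + L, :] = x
        # (B, L, k, C): window w at position t covers xp[t:t+k]
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # sliding_window_view appends the window axis: (B, L, C, k)
        cols = win.reshape(B * L, C * k)  # copies; (C, k) order
        out = cols @ self.W + self.b
        self._cols, self._in_shape = cols, (B, L, C)
        return out.reshape(B, L, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        k, p = self.kernel, self.kernel // 2
        g = dout.reshape(B * L, self.out_ch)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(B, L, C, k)
        dxp = np.zeros((B, L + 2 * p, C), dtype=DTYPE)
        for kk in range(k):
            dxp[:, kk:kk + L, :] += dcols[:, :, :, kk]
        return dxp[:, p:p + L, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        np.maximum(x, DTYPE(0), out=x)
        self._mask = x > 0
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout *= self._mask
        return dout


class MaxPool1d(Layer):
    """Non-overlapping window-2 max pooling over the length axis; a
    trailing odd element is dropped."""

    def __init__(self, window: int = 2):
        if window != 2:
            raise ValueError("only window 2 is supported")
        self.window = window

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // 2
        x0 = x[:, 0:2 * Lo:2, :]
        x1 = x[:, 1:2 * Lo:2, :]
        self._right = x1 > x0
        self._in_shape = (B, L, C)
        return np.where(self._right, x1, x0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        Lo = L // 2
        dx = np.zeros((B, L, C), dtype=DTYPE)
        right = self._right
        dx[:, 0:2 * Lo:2, :] = np.where(right, DTYPE(0), dout)
        dx[:, 1:2 * Lo:2, :] = np.where(right, dout, DTYPE(0))
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    """Affine layer with linear activation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot-uniform
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params_and_grads(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params_and_grads())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params_and_grads, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pg = params_and_grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class AvgPool1d(Layer):
    """Non-overlapping window-2 average pooling over the length axis."""

    def __init__(self, window: int = 2):
        if window != 2:
            raise ValueError("only window 2 is supported")
        self.window = window

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // 2
        self._in_shape = (B, L, C)
        return DTYPE(0.5) * (x[:, 0:2 * Lo:2, :] + x[:, 1:2 * Lo:2, :])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        Lo = L // 2
        dx = np.zeros((B, L, C), dtype=DTYPE)
        half = DTYPE(0.5) * dout
        dx[:, 0:2 * Lo:2, :] = half
        dx[:, 1:2 * Lo:2, :] = half
        return dx
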