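"""Minimal CPU neural-network layers (numpy + BLAS) used by the
compression-state classifier and the 1-D CNN baseline.

Only what those networks need is implemented: stride-1 same-padding
convolutions (2-D in shift-and-accumulate GEMM form, 1-D via im2col),
overlapping max pooling,
ReLU, dense layers, squeeze-and-excitation channel attention, global
average pooling, softmax cross-entropy, and Adam.  All math is float32.

Every layer exposes ``forward(x)`` and ``backward(grad)`` (which must
be called in reverse order of the forwards) and a ``params`` list of
``[weight, grad]`` pairs consumed by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d", "MaxPool2d", "Conv1d", "MaxPool1d", "ReLU", "Dense",
    "GlobalAvgPool", "SEBlock", "softmax", "softmax_cross_entropy", "Adam",
]


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
        np.float32)


class Layer:
    params: list

    def __init__(self):
        self.params = []


class Conv2d(Layer):
    """Stride-1, same-padding 2-D convolution with an odd kernel.

    Activations use NHWC layout (batch, height, width, channels).  The
    convolution is evaluated in shift-and-accumulate form — one
    (C_in x C_out) GEMM per kernel offset on a shifted view of the
    padded input — which avoids materializing the k^2-fold im2col
    buffer and is markedly faster for small kernels on a CPU.
    """

    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = _he_init(rng, (k, k, c_in, c_out), c_in * k * k)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.w, self.gw], [self.b, self.gb]]

    def forward(self, x):
        b, h, w, c = x.shape
        self.x_shape = x.shape
        p = self.k // 2
        self.xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((b, h, w, self.c_out), dtype=np.float32)
        out[...] = self.b
        for i in range(self.k):
            for j in range(self.k):
                out += self.xp[:, i:i + h, j:j + w, :] @ self.w[i, j]
        return out

    def backward(self, grad):
        b, h, w, _ = self.x_shape
        g2 = grad.reshape(-1, self.c_out)
        self.gb[...] = g2.sum(axis=0)
        dxp = np.zeros_like(self.xp)
        for i in range(self.k):
            for j in range(self.k):
                sl = np.s_[:, i:i + h, j:j + w, :]
                self.gw[i, j] = self.xp[sl].reshape(-1, self.c_in).T @ g2
                dxp[sl] += grad @ self.w[i, j].T
        p = self.k // 2
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, :]


class MaxPool2d(Layer):
    """3x3/stride-2/pad-1 (or stride-1 same) max pooling, NHWC."""

    def __init__(self, k=3, stride=2, pad=1):
        super().__init__()
        self.k, self.s, self.p = k, stride, pad

    def forward(self, x):
        b, h, w, c = x.shape
        self.x_shape = x.shape
        xp = np.pad(x, ((0, 0), (self.p, self.p), (self.p, self.p), (0, 0)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        win = win[:, ::self.s, ::self.s]
        b_, ho, wo, c_, _, _ = win.shape
        flat = win.reshape(b, ho, wo, c, self.k * self.k)
        self.am = np.argmax(flat, axis=-1)
        self.out_shape = (b, ho, wo, c)
        return np.max(flat, axis=-1)

    def backward(self, grad):
        b, h, w, c = self.x_shape
        gpad = np.zeros((b, h + 2 * self.p, w + 2 * self.p, c),
                        dtype=grad.dtype)
        bi, oi, oj, ci = np.indices(self.out_shape)
        pr = oi * self.s + self.am // self.k
        pc = oj * self.s + self.am % self.k
        np.add.at(gpad, (bi, pr, pc, ci), grad)
        return gpad[:, self.p: self.p + h, self.p: self.p + w]


class Conv1d(Layer):
    """Stride-1, same-padding 1-D convolution with an odd kernel."""

    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = _he_init(rng, (c_out, c_in * k), c_in * k)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.w, self.gw], [self.b, self.gb]]

    def _cols(self, x):
        b, c, n = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)  # (B, C, N, k)
        return np.ascontiguousarray(
            win.transpose(0, 2, 1, 3)).reshape(b * n, c * self.k)

    def forward(self, x):
        self.x_shape = x.shape
        b, c, n = x.shape
        self.cols = self._cols(x)
        out = self.cols @ self.w.T + self.b
        return np.ascontiguousarray(
            out.reshape(b, n, self.c_out).transpose(0, 2, 1))

    def backward(self, grad):
        b, _, n = self.x_shape
        g2 = np.ascontiguousarray(
            grad.transpose(0, 2, 1)).reshape(b * n, self.c_out)
        self.gw[...] = g2.T @ self.cols
        self.gb[...] = g2.sum(axis=0)
        wk = self.w.reshape(self.c_out, self.c_in, self.k)
        w_flip = wk[:, :, ::-1].transpose(1, 0, 2).reshape(self.c_in, -1)
        p = self.k // 2
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(gp, self.k, axis=2)
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 1, 3)).reshape(b * n, -1)
        dx = cols @ w_flip.T
        return np.ascontiguousarray(dx.reshape(b, n, self.c_in)
                                    .transpose(0, 2, 1))


class MaxPool1d(Layer):
    """Non-overlapping 1-D max pooling (kernel = stride = 2)."""

    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        b, c, n = x.shape
        self.n = n
        n_trim = (n // self.k) * self.k
        self.n_trim = n_trim
        xr = x[:, :, :n_trim].reshape(b, c, n_trim // self.k, self.k)
        self.am = np.argmax(xr, axis=-1)
        return np.max(xr, axis=-1)

    def backward(self, grad):
        b, c, no = grad.shape
        dx = np.zeros((b, c, self.n), dtype=grad.dtype)
        bi, ci, oi = np.indices(grad.shape)
        dx[bi, ci, oi * self.k + self.am] = grad
        return dx


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.w = _he_init(rng, (n_out, n_in), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.w, self.gw], [self.b, self.gb]]

    def forward(self, x):
        self.x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw[...] = grad.T @ self.x
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w


class GlobalAvgPool(Layer):
    """NHWC (B, H, W, C) -> (B, C) mean over the spatial axes."""

    def forward(self, x):
        self.x_shape = x.shape
        self.n_spatial = x.shape[1] * x.shape[2]
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        return np.broadcast_to(
            grad[:, None, None, :] / self.n_spatial, self.x_shape).copy()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Global average pool -> bottleneck dense (C -> C/r) -> ReLU ->
    dense (C/r -> C) -> sigmoid gate multiplying each channel.
    """

    def __init__(self, c, rng, reduction=4):
        super().__init__()
        hidden = max(c // reduction, 4)
        self.fc1 = Dense(c, hidden, rng)
        self.fc2 = Dense(hidden, c, rng)
        self.params = self.fc1.params + self.fc2.params

    def forward(self, x):
        self.x = x
        self.hw = x.shape[1] * x.shape[2]
        z = x.mean(axis=(1, 2))
        h = self.fc1.forward(z)
        self.h_mask = h > 0
        self.s = _sigmoid(self.fc2.forward(h * self.h_mask))
        self.gate = self.s[:, None, None, :]
        return x * self.gate

    @property
    def last_gate(self):
        """Attention weights of the most recent forward pass (B, C)."""
        return self.s

    def backward(self, grad):
        dx = grad * self.gate
        ds = (grad * self.x).sum(axis=(1, 2))
        dpre = ds * self.s * (1.0 - self.s)
        dh = self.fc2.backward(dpre) * self.h_mask
        dz = self.fc1.backward(dh)
        dx += dz[:, None, None, :] / self.hw
        return dx


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
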