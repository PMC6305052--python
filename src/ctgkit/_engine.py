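"""Minimal numpy neural-network engine backing the MKNet/MKRNN builders.

Layers implement ``forward(x, train)`` / ``backward(dout)`` and expose
``params``/``grads`` lists.  Convolutions use im2col with a BLAS matmul;
the LSTM runs classic truncated-free BPTT over the full sequence.  Two
optimizers are provided (RMSprop, Adagrad) with softmax cross-entropy
loss.  Sized for desk-scale experiments on one CPU, not for GPU-scale
training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float64) * np.sqrt(2.0 / fan_in)


class Conv2D:
    """Same/valid 2-D convolution with optional ReLU, stride (sh, sw)."""

    def __init__(self, in_ch, filters, kernel, stride=(1, 1), padding="same",
                 relu=True, rng=None):
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.relu = relu
        self.in_ch = in_ch
        self.filters = filters
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (filters, in_ch * kh * kw), in_ch * kh * kw)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad(self, x):
        kh, kw = self.kernel
        if self.padding == "same":
            ph, pw = kh // 2, kw // 2
            return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))), (ph, pw)
        return x, (0, 0)

    def forward(self, x, train=False):
        n, c, _, _ = x.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        xp, _ = self._pad(x)
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        _, _, ho, wo, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
        out = cols @ self.W.T + self.b
        out = out.reshape(n, ho, wo, self.filters).transpose(0, 3, 1, 2)
        if self.relu:
            self._relu_mask = out > 0
            out = out * self._relu_mask
        self._cache = (cols, x.shape, xp.shape, (ho, wo))
        return out

    def backward(self, dout):
        cols, x_shape, xp_shape, (ho, wo) = self._cache
        n = x_shape[0]
        kh, kw = self.kernel
        sh, sw = self.stride
        if self.relu:
            dout = dout * self._relu_mask
        d2 = dout.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.filters)
        self.grads[0][...] = np.einsum("npf,npk->fk", d2, cols)
        self.grads[1][...] = d2.sum(axis=(0, 1))
        dcols = (d2 @ self.W).reshape(n, ho, wo, self.in_ch, kh, kw)
        dxp = np.zeros(xp_shape)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        ph = (xp_shape[2] - x_shape[2]) // 2
        pw = (xp_shape[3] - x_shape[3]) // 2
        if ph or pw:
            return dxp[:, :, ph : ph + x_shape[2], pw : pw + x_shape[3]]
        return dxp


class MaxPool2D:
    """2x2 stride-2 max pooling (odd trailing rows/columns are dropped)."""

    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, : ho * 2, : wo * 2]
        patches = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = patches.reshape(n, c, ho, wo, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        ho, wo = h // 2, w // 2
        dflat = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, : ho * 2, : wo * 2] = (
            dflat.reshape(n, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * 2, wo * 2)
        )
        return dx


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, in_dim, units, relu=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.relu = relu
        self.W = _he_init(rng, (in_dim, units), in_dim)
        self.b = np.zeros(units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.W + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate, rng=None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class LSTM:
    """Single recurrent layer returning the final hidden state.

    Input (N, T, D); gate order in the stacked weight matrix is
    input, forget, cell, output.  ``dropout`` masks the input, and
    ``recurrent_dropout`` masks the hidden state fed to the gates, both
    only during training (per-sequence masks, constant over time).
    """

    def __init__(self, in_dim, units, dropout=0.0, recurrent_dropout=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.in_dim = in_dim
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.rng = rng
        scale = 1.0 / np.sqrt(in_dim + units)
        self.W = rng.standard_normal((in_dim + units, 4 * units)) * scale
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        n, t, d = x.shape
        u = self.units
        if train and self.dropout > 0:
            xm = (self.rng.random((n, 1, d)) >= self.dropout) / (1 - self.dropout)
            x = x * xm
        self._hm = None
        if train and self.recurrent_dropout > 0:
            self._hm = (self.rng.random((n, u)) >= self.recurrent_dropout) / (
                1 - self.recurrent_dropout
            )
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._steps = []
        self._x = x
        for k in range(t):
            hd = h * self._hm if self._hm is not None else h
            z = np.concatenate([x[:, k, :], hd], axis=1) @ self.W + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c = f * c + i * g
            h = o * np.tanh(c)
            self._steps.append((x[:, k, :], hd, i, f, g, o, c.copy(), h.copy()))
        return h

    def backward(self, dout):
        n, t, d = self._x.shape
        u = self.units
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dh = dout
        dc = np.zeros((n, u))
        dx = np.zeros_like(self._x)
        for k in range(t - 1, -1, -1):
            xk, hd, i, f, g, o, c, _h = self._steps[k]
            c_prev = self._steps[k - 1][6] if k > 0 else np.zeros((n, u))
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            inp = np.concatenate([xk, hd], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ self.W.T
            dx[:, k, :] = dinp[:, :d]
            dh_prev = dinp[:, d:]
            if self._hm is not None:
                dh_prev = dh_prev * self._hm
            dh = dh_prev
            dc = dc * f
        self.grads[0][...] = dW
        self.grads[1][...] = db
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class Network:
    """Ordered layer stack with softmax cross-entropy training head."""

    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    def train_step(self, x, y):
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        n = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return loss, probs


class RMSprop:
    def __init__(self, lr=1e-3, decay=0.9, eps=1e-8):
        self.lr, self.decay, self.eps = lr, decay, eps
        self._cache = None

    def step(self, params, grads):
        if self._cache is None:
            self._cache = [np.zeros_like(p) for p in params]
        for p, g, c in zip(params, grads, self._cache):
            c *= self.decay
            c += (1 - self.decay) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


class Adagrad:
    def __init__(self, lr=1e-2, eps=1e-8):
        self.lr, self.eps = lr, eps
        self._cache = None

    def step(self, params, grads):
        if self._cache is None:
            self._cache = [np.zeros_like(p) for p in params]
        for p, g, c in zip(params, grads, self._cache):
            c += g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


OPTIMIZERS = {"rmsprop": RMSprop, "adagrad": Adagrad}
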