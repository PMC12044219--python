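"""Minimal feed-forward / recurrent network core with manual backprop.

Implements exactly the pieces the gait models need — dense, 2-D valid
convolution on (height, 1) maps, 2x1 max-pooling, an LSTM, and
squeeze-and-excitation channel gating — together with softmax
cross-entropy, mean-squared-error, and an Adam optimizer with an
epoch-stepped learning-rate schedule.  Everything is plain float64 numpy;
gradients are exact (verified by finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray) -> None:
        self.v = np.asarray(value, float)
        self.g = np.zeros_like(self.v)

    @property
    def size(self) -> int:
        return self.v.size


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int,
            fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers

class Dense:
    """Affine layer with optional ReLU, input (N, n_in) -> (N, n_out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = False, name: str = "dense") -> None:
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self.relu = relu
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W.v + self.b.v
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        self.W.g += self._x.T @ dout
        self.b.g += dout.sum(axis=0)
        return dout @ self.W.v.T


class Conv2dH:
    """Valid convolution along height of (N, H, 1, C_in) maps.

    The kernel is a full ``kh x kw`` window (so the trainable-parameter
    count is ``kh*kw*C_in*C_out + C_out``); with unit-width input and
    zero-padded width only the centre kernel column sees data, making the
    operation an efficient height-wise convolution.
    """

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int,
                 rng: np.random.Generator, relu: bool = True,
                 name: str = "conv") -> None:
        fan_in = kh * kw * c_in
        self.W = Param(_glorot(rng, (kh, kw, c_in, c_out), fan_in, c_out))
        self.b = Param(np.zeros(c_out))
        self.kh, self.kw = kh, kw
        self.c_in, self.c_out = c_in, c_out
        self.relu = relu
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, H, C_in) -> (N, H - kh + 1, C_out)
        self._x = x
        kc = self.kw // 2
        ho = x.shape[1] - self.kh + 1
        z = np.broadcast_to(self.b.v, (x.shape[0], ho, self.c_out)).copy()
        for dh in range(self.kh):
            z += x[:, dh:dh + ho, :] @ self.W.v[dh, kc]
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        x = self._x
        kc = self.kw // 2
        ho = dout.shape[1]
        dx = np.zeros_like(x)
        self.b.g += dout.sum(axis=(0, 1))
        for dh in range(self.kh):
            xs = x[:, dh:dh + ho, :]
            self.W.g[dh, kc] += np.einsum("nhc,nhd->cd", xs, dout)
            dx[:, dh:dh + ho, :] += dout @ self.W.v[dh, kc].T
        return dx


class MaxPool2:
    """2x1 max pooling along height: (N, H, C) -> (N, H//2, C)."""

    name = "maxpool"

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, c = x.shape
        ho = h // 2
        pairs = x[:, :2 * ho, :].reshape(n, ho, 2, c)
        self._arg = pairs.argmax(axis=2)
        self._shape = x.shape
        return pairs.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, ho, c = dout.shape
        dpairs = np.zeros((n, ho, 2, c))
        np.put_along_axis(dpairs, self._arg[:, :, None, :], dout[:, :, None, :],
                          axis=2)
        dx = np.zeros(self._shape)
        dx[:, :2 * ho, :] = dpairs.reshape(n, 2 * ho, c)
        return dx


class SEGate:
    """Squeeze-and-excitation channel gate.

    Attention weights are computed from the *source* maps (global average
    pool over height, dense to a bottleneck with ReLU, dense to the target
    channel count, sigmoid) and applied multiplicatively to the *target*
    maps.  Source and target may be the same tensor (classic SE) or two
    stages of a convolutional stack.
    """

    def __init__(self, c_src: int, c_tgt: int, bottleneck: int,
                 rng: np.random.Generator, name: str = "se") -> None:
        self.fc1 = Dense(c_src, bottleneck, rng, relu=True, name=f"{name}_fc1")
        self.fc2 = Dense(bottleneck, c_tgt, rng, relu=False,
                         name=f"{name}_fc2")
        self.name = name

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def weights(self, src: np.ndarray) -> np.ndarray:
        """Attention weights in (0, 1), shape (N, c_tgt)."""
        self._src_h = src.shape[1]
        s = src.mean(axis=1)
        self._w = sigmoid(self.fc2.forward(self.fc1.forward(s)))
        return self._w

    def forward(self, src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
        self._tgt = tgt
        w = self.weights(src)
        return tgt * w[:, None, :]

    def backward(self, dout: np.ndarray):
        w = self._w
        dtgt = dout * w[:, None, :]
        dw = (dout * self._tgt).sum(axis=1)
        dz = dw * w * (1.0 - w)
        ds = self.fc1.backward(self.fc2.backward(dz))
        dsrc_pooled = ds / self._src_h
        dsrc = np.repeat(dsrc_pooled[:, None, :], self._src_h, axis=1)
        return dsrc, dtgt


class LSTM:
    """Single-layer LSTM over (N, T, D); returns the final hidden state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 name: str = "lstm") -> None:
        h = n_hidden
        self.Wx = Param(_glorot(rng, (n_in, 4 * h), n_in, h))
        self.Wh = Param(_glorot(rng, (h, 4 * h), h, h))
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias
        self.b = Param(b)
        self.n_hidden = h
        self.name = name

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        h = self.n_hidden
        hs = np.zeros((n, h))
        cs = np.zeros((n, h))
        self._x = x
        self._cache = []
        for step in range(t):
            xt = x[:, step, :]
            z = xt @ self.Wx.v + hs @ self.Wh.v + self.b.v
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = sigmoid(z[:, 3 * h:])
            c_new = f * cs + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((xt, hs, cs, i, f, g, o, tanh_c))
            hs, cs = h_new, c_new
        return hs

    def backward(self, dh: np.ndarray) -> np.ndarray:
        h = self.n_hidden
        x = self._x
        n, t, d = x.shape
        dx = np.zeros_like(x)
        dc = np.zeros((n, h))
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[step]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.hstack([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ])
            self.Wx.g += xt.T @ dz
            self.Wh.g += h_prev.T @ dz
            self.b.g += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.Wx.v.T
            dh = dz @ self.Wh.v.T
            dc = dc * f
        return dx


# ---------------------------------------------------------------------------
# losses

def softmax_ce_loss(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy from logits; returns (loss, dlogits)."""
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.log(np.clip(p[np.arange(n), y], eps, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def mse_grad(pred: np.ndarray, true: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - true
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, params: list[Param], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float = 5.0) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.g ** 2)) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    p.g *= scale
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.g
            v[...] = b2 * v + (1 - b2) * p.g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.v -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop

def train_network(net, X: np.ndarray, y: np.ndarray, *, loss: str,
                  epochs: int, lr: float, batch_size: int = 128,
                  lr_drop_factor: float = 0.1,
                  lr_drop_period: int | None = None,
                  shuffle: bool = True, seed: int = 0,
                  clip_norm: float = 5.0) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss trace.

    The learning rate is multiplied by ``lr_drop_factor`` every
    ``lr_drop_period`` epochs.  Raises on a non-finite loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr, clip_norm=clip_norm)
    n = len(X)
    losses = []
    for epoch in range(epochs):
        if lr_drop_period:
            lr_e = lr * lr_drop_factor ** (epoch // lr_drop_period)
        else:
            lr_e = lr
        order = rng.permutation(n) if shuffle else np.arange(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            opt.zero_grad()
            out = net.forward(xb)
            if loss == "softmax_ce":
                lval, dout = softmax_ce_loss(out, yb)
            elif loss == "mse":
                lval, dout = mse_grad(out[:, 0], yb)
                dout = dout[:, None]
            else:
                raise ValueError(f"unknown loss {loss!r}")
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {lval}")
            net.backward(dout)
            opt.step(lr_e)
            total += lval * len(idx)
        losses.append(total / n)
    return losses
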