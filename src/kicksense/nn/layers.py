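"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the three window classifiers need: valid 1-D convolution,
max-pooling, dropout, dense with optional L1/L2 kernel penalties, ReLU,
batch feature normalization, a last-output LSTM with separate input-path and
recurrent-path biases, and a convolutional LSTM on a 1×W spatial grid.

Conventions: batches are leading, time-major layouts ``(N, L, C)``; every
layer exposes ``params`` / ``grads`` dicts, ``forward(x, training, rng)`` and
``backward(dy)``; gradients are averaged over the batch by the loss, so the
optimizer applies them directly. Gradient correctness is pinned by finite-
difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "BatchNorm",
    "LSTMLast",
    "ConvLSTM",
    "softmax",
    "softmax_xent",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        """Parameter count as reported in architecture tables."""
        return int(sum(p.size for p in self.params.values()))

    def astype(self, dtype) -> None:
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L-k+1, k*C) patch matrix for valid convolution."""
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (N, Lout, C, k)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2]
    )


def _col2im(dcols: np.ndarray, n: int, length: int, channels: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    dx = np.zeros((n, length, channels), dtype=dcols.dtype)
    d = dcols.reshape(n, length - k + 1, k, channels)
    for j in range(k):
        dx[:, j : j + length - k + 1, :] += d[:, :, j, :]
    return dx


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution with bias: (N, L, Cin) -> (N, L-k+1, Cout)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k = kernel_size
        self.cin = in_channels
        self.cout = filters
        fan_in = kernel_size * in_channels
        self.params["W"] = glorot_uniform(rng, fan_in, filters, (fan_in, filters))
        self.params["b"] = np.zeros(filters)

    def forward(self, x, training=False, rng=None):
        self._cols = _im2col(x, self.k)
        self._in_shape = x.shape
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        n, lout, _ = dy.shape
        self.grads["W"] = self._cols.reshape(-1, self.k * self.cin).T @ dy.reshape(
            -1, self.cout
        )
        self.grads["b"] = dy.sum(axis=(0, 1))
        dcols = dy @ self.params["W"].T
        return _col2im(dcols, n, self._in_shape[1], self.cin, self.k)

    def out_length(self, length: int) -> int:
        return length - self.k + 1


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; trailing remainder dropped."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.p = pool_size

    def forward(self, x, training=False, rng=None):
        n, length, c = x.shape
        lout = length // self.p
        self._in_shape = x.shape
        xr = x[:, : lout * self.p, :].reshape(n, lout, self.p, c)
        self._arg = np.argmax(xr, axis=2)
        return np.max(xr, axis=2)

    def backward(self, dy):
        n, length, c = self._in_shape
        lout = length // self.p
        dxr = np.zeros((n, lout, self.p, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, length, c), dtype=dy.dtype)
        dx[:, : lout * self.p, :] = dxr.reshape(n, lout * self.p, c)
        return dx

    def out_length(self, length: int) -> int:
        return length // self.p


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Affine layer; optional L1/L2 penalties on the kernel (added to grads)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 l1: float = 0.0, l2: float = 0.0):
        super().__init__()
        self.l1, self.l2 = l1, l2
        self.params["W"] = glorot_uniform(
            rng, in_features, out_features, (in_features, out_features)
        )
        self.params["b"] = np.zeros(out_features)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] = self._x.T @ dy
        if self.l1:
            self.grads["W"] = self.grads["W"] + self.l1 * np.sign(W)
        if self.l2:
            self.grads["W"] = self.grads["W"] + 2.0 * self.l2 * W
        self.grads["b"] = dy.sum(axis=0)
        return dy @ W.T

    def penalty(self) -> float:
        W = self.params["W"]
        return float(self.l1 * np.abs(W).sum() + self.l2 * np.square(W).sum())


class BatchNorm(Layer):
    """Feature normalization over the batch axis for (N, F) inputs.

    Holds 2 learned (gamma, beta) and 2 running (mean, var) parameters per
    feature; all four are reported in the parameter count, matching the
    bookkeeping of mainstream frameworks.
    """

    def __init__(self, features: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(features)
        self.params["beta"] = np.zeros(features)
        self.params["running_mean"] = np.zeros(features)
        self.params["running_var"] = np.ones(features)
        self.non_trainable = ("running_mean", "running_var")

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.params["running_mean"] = m * self.params["running_mean"] + (1 - m) * mu
            self.params["running_var"] = m * self.params["running_var"] + (1 - m) * var
        else:
            mu = self.params["running_mean"]
            var = self.params["running_var"]
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        self.grads["gamma"] = (dy * self._xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        self.grads["running_mean"] = np.zeros_like(self.params["running_mean"])
        self.grads["running_var"] = np.zeros_like(self.params["running_var"])
        g = dy * self.params["gamma"]
        if not self._training:
            return g * self._istd
        n = dy.shape[0]
        return (self._istd / n) * (
            n * g - g.sum(axis=0) - self._xhat * (g * self._xhat).sum(axis=0)
        )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTMLast(Layer):
    """Single LSTM layer returning the final hidden state: (N, T, D) -> (N, U).

    Uses two independent bias vectors per gate set (input-path and
    recurrent-path), so the parameter count is ``4U(D + U) + 2·4U``.
    Gate order is (input, forget, cell, output). Biases start chrono-style
    (forget +``chrono_bias``, input −``chrono_bias``) so the initial memory
    time constant spans a substantial part of the window — with the default
    the classified event is still visible in the final state at
    initialization, which is what makes the layer trainable on windows whose
    event sits at the center.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 chrono_bias: float = 4.0):
        super().__init__()
        self.d, self.u = input_dim, units
        self.params["Wx"] = glorot_uniform(rng, input_dim, units, (input_dim, 4 * units))
        self.params["Wh"] = np.concatenate(
            [orthogonal(rng, units) for _ in range(4)], axis=1
        )
        b_i = np.zeros(4 * units)
        b_i[:units] = -chrono_bias
        b_i[units : 2 * units] = chrono_bias
        self.params["b_i"] = b_i
        self.params["b_h"] = np.zeros(4 * units)

    def forward(self, x, training=False, rng=None):
        n, T, _ = x.shape
        u = self.u
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        bias = self.params["b_i"] + self.params["b_h"]
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        zx_all = x @ Wx  # (N, T, 4U), hoisted out of the loop
        for t in range(T):
            z = zx_all[:, t, :] + h @ Wh + bias
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            self._cache.append((h, c_prev, i, f, g, o, tc))
            h = o * tc
        return h

    def backward(self, dy):
        n, T, _ = self._x.shape
        u = self.u
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * u, dtype=dy.dtype)
        dx = np.zeros_like(self._x)
        dh = dy.copy()
        dc = np.zeros((n, u), dtype=dy.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += self._x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"], self.grads["Wh"] = dWx, dWh
        self.grads["b_i"] = db
        self.grads["b_h"] = db.copy()
        return dx


class ConvLSTM(Layer):
    """Convolutional LSTM over a (1, W) spatial grid, returning the final state.

    Input ``(N, T, W, C)``; the input-to-state convolution is valid
    (W -> W-k+1), the state-to-state convolution is same-padded, one bias per
    gate: ``4F(k(C + F) + 1)`` parameters. Output ``(N, W-k+1, F)``.
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cin, self.f, self.k = in_channels, filters, kernel_size
        fan_in = kernel_size * in_channels
        self.params["Wx"] = glorot_uniform(
            rng, fan_in, filters, (fan_in, 4 * filters)
        )
        self.params["Wh"] = glorot_uniform(
            rng, kernel_size * filters, filters, (kernel_size * filters, 4 * filters)
        )
        # unit forget bias: with only ~8 recurrent steps the classic init
        # keeps the whole sequence in reach, unlike the 400-step case
        b = np.zeros(4 * filters)
        b[filters : 2 * filters] = 1.0
        self.params["b"] = b
        self._pad = (kernel_size - 1) // 2, kernel_size - 1 - (kernel_size - 1) // 2

    def forward(self, x, training=False, rng=None):
        n, T, w, _ = x.shape
        f, k = self.f, self.k
        wout = w - k + 1
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, wout, f), dtype=x.dtype)
        c = np.zeros((n, wout, f), dtype=x.dtype)
        self._x = x
        self._cache = []
        pl, pr = self._pad
        for t in range(T):
            xcols = _im2col(x[:, t], k)  # (N, wout, k*cin)
            hp = np.pad(h, ((0, 0), (pl, pr), (0, 0)))
            hcols = _im2col(hp, k)  # (N, wout, k*f)
            z = xcols @ Wx + hcols @ Wh + b
            i = _sigmoid(z[..., :f])
            fg = _sigmoid(z[..., f : 2 * f])
            g = np.tanh(z[..., 2 * f : 3 * f])
            o = _sigmoid(z[..., 3 * f :])
            c_prev = c
            c = fg * c_prev + i * g
            tc = np.tanh(c)
            self._cache.append((xcols, hcols, h, c_prev, i, fg, g, o, tc))
            h = o * tc
        return h

    def backward(self, dy):
        n, T, w, cin = self._x.shape
        f, k = self.f, self.k
        wout = w - k + 1
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * f, dtype=dy.dtype)
        dx = np.zeros_like(self._x)
        dh = dy.copy()
        dc = np.zeros((n, wout, f), dtype=dy.dtype)
        pl, pr = self._pad
        for t in range(T - 1, -1, -1):
            xcols, hcols, h_prev, c_prev, i, fg, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * fg * (1 - fg),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=2,
            )
            dzf = dz.reshape(-1, 4 * f)
            dWx += xcols.reshape(-1, k * cin).T @ dzf
            dWh += hcols.reshape(-1, k * f).T @ dzf
            db += dzf.sum(axis=0)
            dx[:, t] = _col2im(dz @ Wx.T, n, w, cin, k)
            dhp = _col2im(dz @ Wh.T, n, wout + pl + pr, f, k)
            dh = dhp[:, pl : pl + wout, :]
            dc = dc * fg
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n
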