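"""Minimal numpy neural-network core used by the backbones, fusion models and surrogate.

Everything here is deliberately small: the models trained in this package are
desk-scale (tens of thousands of parameters), so a compact set of layers with
explicit forward/backward passes and an Adam optimizer is sufficient and keeps
the whole pipeline dependency-light and deterministic.

Conventions
-----------
* Images are NHWC float arrays, pixel values in [-1, 1].
* Every layer exposes ``forward(x, train)``, ``backward(dout)`` and ``params()``
  (a list of :class:`Param`).  Gradients accumulate into ``Param.grad`` during
  ``backward`` and are consumed by :class:`Adam`.
* All random initialisation draws from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "Conv2d",
    "BatchNorm",
    "Dropout",
    "relu",
    "sigmoid",
    "ACTIVATIONS",
    "softmax",
    "Adam",
    "LSTMRegressor",
]


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _relu_f(x):
    return np.maximum(x, 0.0)


def _relu_b(x, y, dy):
    return dy * (x > 0.0)


def _sigmoid_f(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sigmoid_b(x, y, dy):
    return dy * y * (1.0 - y)


class _Activation:
    def __init__(self, name, f, b):
        self.name, self._f, self._b = name, f, b

    def forward(self, x):
        self._x = x
        self._y = self._f(x)
        return self._y

    def backward(self, dy):
        return self._b(self._x, self._y, dy)

    def __call__(self, x):
        return self._f(x)


def relu() -> _Activation:
    return _Activation("relu", _relu_f, _relu_b)


def sigmoid() -> _Activation:
    return _Activation("sigmoid", _sigmoid_f, _sigmoid_b)


#: activation functions available to fusion layers, index order matters
ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid}
ACTIVATION_NAMES = tuple(ACTIVATIONS)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Dense:
    """Fully connected layer with optional L1/L2 weight penalties."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 l1: float = 0.0, l2: float = 0.0):
        self.W = Param(glorot(rng, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.l1 = l1
        self.l2 = l2

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        if self.l2:
            self.W.grad += 2.0 * self.l2 * self.W.value
        if self.l1:
            self.W.grad += self.l1 * np.sign(self.W.value)
        return dy @ self.W.value.T

    def params(self):
        return [self.W, self.b]

    def penalty(self) -> float:
        p = 0.0
        if self.l2:
            p += self.l2 * float((self.W.value ** 2).sum())
        if self.l1:
            p += self.l1 * float(np.abs(self.W.value).sum())
        return p


def _im2col(x, k, stride):
    n, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    shape = (n, ho, wo, k, k, c)
    strides = (s0, s1 * stride, s2 * stride, s1, s2, s3)
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(cols).reshape(n * ho * wo, k * k * c), ho, wo


class Conv2d:
    """3x3 valid convolution (NHWC) via im2col; stride controls downsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2):
        self.k, self.stride, self.c_in = k, stride, c_in
        self.W = Param(glorot(rng, (k * k * c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def forward(self, x, train=False):
        self._xshape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride)
        self._cols = cols
        self._ho, self._wo = ho, wo
        y = cols @ self.W.value + self.b.value
        return y.reshape(x.shape[0], ho, wo, -1)

    def backward(self, dy):
        n, ho, wo, f = dy.shape
        dyf = dy.reshape(n * ho * wo, f)
        self.W.grad += self._cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(n, ho, wo, self.k, self.k, self.c_in)
        dx = np.zeros(self._xshape)
        st = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + ho * st:st, j:j + wo * st:st, :] += dcols[:, :, :, i, j, :]
        return dx

    def params(self):
        return [self.W, self.b]


class BatchNorm:
    """Batch normalisation over all axes but the last (channel) axis."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)

    def forward(self, x, train=False):
        self._shape = x.shape
        xf = x.reshape(-1, x.shape[-1])
        if train:
            mean = xf.mean(axis=0)
            var = xf.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (xf - mean) / self._std
        y = self.gamma.value * self._xhat + self.beta.value
        return y.reshape(self._shape)

    def backward(self, dy):
        dyf = dy.reshape(-1, dy.shape[-1])
        m = dyf.shape[0]
        self.gamma.grad += (dyf * self._xhat).sum(axis=0)
        self.beta.grad += dyf.sum(axis=0)
        dxhat = dyf * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=0)
              - self._xhat * (dxhat * self._xhat).mean(axis=0)) / self._std
        return dx.reshape(self._shape)

    def params(self):
        return [self.gamma, self.beta]


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class GlobalAvgPool:
    """Mean over spatial axes of an NHWC tensor."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).copy()

    def params(self):
        return []


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


# ---------------------------------------------------------------------------
# LSTM sequence regressor (the search surrogate)
# ---------------------------------------------------------------------------

class LSTMRegressor:
    """Embedding (zero-masked) -> LSTM -> single sigmoid unit.

    Token 0 is padding: masked timesteps carry the hidden state through
    unchanged, so right-padded sequences of different true lengths share one
    batch.  Trained with Adam and mean squared error.
    """

    def __init__(self, vocab_size: int, seed: int,
                 embed_dim: int = 100, hidden: int = 100):
        rng = np.random.default_rng(seed)
        self.H = hidden
        self.E = Param(rng.normal(0.0, 0.05, size=(vocab_size, embed_dim)))
        self.Wx = Param(glorot(rng, (embed_dim, 4 * hidden)))
        self.Wh = Param(glorot(rng, (hidden, 4 * hidden)))
        self.bg = Param(np.zeros(4 * hidden))
        # forget-gate bias 1: standard LSTM initialisation
        self.bg.value[hidden:2 * hidden] = 1.0
        self.Wo = Param(glorot(rng, (hidden, 1)))
        self.bo = Param(np.zeros(1))
        self._rng = rng
        self._fitted = False

    def _params(self):
        return [self.E, self.Wx, self.Wh, self.bg, self.Wo, self.bo]

    def _forward(self, tokens: np.ndarray):
        n, T = tokens.shape
        H = self.H
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        for t in range(T):
            tok = tokens[:, t]
            mask = (tok > 0).astype(np.float64)[:, None]
            x = self.E.value[tok]
            gates = x @ self.Wx.value + h @ self.Wh.value + self.bg.value
            i = _sigmoid_f(gates[:, :H])
            f = _sigmoid_f(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = _sigmoid_f(gates[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            h_next = mask * h_new + (1 - mask) * h
            c_next = mask * c_new + (1 - mask) * c
            cache.append((tok, mask, x, h, c, i, f, g, o, c_new))
            h, c = h_next, c_next
        z = h @ self.Wo.value + self.bo.value
        y = _sigmoid_f(z)
        return y[:, 0], (cache, h, y)

    def _backward(self, tokens, ctx, dy):
        cache, h_last, y = ctx
        H = self.H
        dz = dy[:, None] * y * (1.0 - y)
        self.Wo.grad += h_last.T @ dz
        self.bo.grad += dz.sum(axis=0)
        dh = dz @ self.Wo.value.T
        dc = np.zeros_like(dh)
        for t in range(len(cache) - 1, -1, -1):
            tok, mask, x, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            dh_new = dh * mask
            dc_new = dc * mask
            dh_prev_skip = dh * (1 - mask)
            dc_prev_skip = dc * (1 - mask)
            tanh_c = np.tanh(c_new)
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1 - tanh_c ** 2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc_prev = dc_new * f
            dgates = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dx = dgates @ self.Wx.value.T
            self.Wx.grad += x.T @ dgates
            self.Wh.grad += h_prev.T @ dgates
            self.bg.grad += dgates.sum(axis=0)
            np.add.at(self.E.grad, tok, dx)
            dh = dgates @ self.Wh.value.T + dh_prev_skip
            dc = dc_prev + dc_prev_skip

    def fit(self, tokens: np.ndarray, targets: np.ndarray,
            epochs: int = 50, batch_size: int = 64, lr: float = 1e-3) -> float:
        """Train on the full result set; returns final epoch mean MSE."""
        tokens = np.asarray(tokens, dtype=np.intp)
        targets = np.asarray(targets, dtype=np.float64)
        n = tokens.shape[0]
        opt = Adam(self._params(), lr=lr)
        last = np.nan
        for _ in range(epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = tokens[idx], targets[idx]
                pred, ctx = self._forward(xb)
                err = pred - yb
                losses.append(float((err ** 2).mean()))
                opt.zero_grad()
                self._backward(xb, ctx, 2.0 * err / len(idx))
                opt.step()
            last = float(np.mean(losses))
        self._fitted = True
        return last

    def predict(self, tokens: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("surrogate must be fitted before scoring")
        pred, _ = self._forward(np.asarray(tokens, dtype=np.intp))
        return pred

    # -- checkpointing ------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        names = ["E", "Wx", "Wh", "bg", "Wo", "bo"]
        return {n: getattr(self, n).value.copy() for n in names}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for n, v in weights.items():
            getattr(self, n).value[...] = v
        self._fitted = True
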