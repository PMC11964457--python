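"""A compact NumPy neural-network engine: the layers, activation and
optimiser needed by the two gait classifiers.

Every layer implements ``forward(x, ...)`` caching what its ``backward(d)``
needs; parameter gradients accumulate into ``Param.grad`` (callers zero them
between minibatches).  Everything runs in float32, single pass, fully
deterministic given the caller's ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

# Standard self-normalising constants of the scaled exponential linear unit.
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


def selu(x):
    """SELU(x) = lambda * x for x > 0, lambda * alpha * (exp(x) - 1) otherwise."""
    x = np.asarray(x)
    return np.where(x > 0, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * np.expm1(x))


def selu_grad(x):
    x = np.asarray(x)
    return np.where(x > 0, SELU_LAMBDA, SELU_LAMBDA * SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def _selu_forward(z: np.ndarray) -> tuple[np.ndarray, tuple]:
    """In-place SELU over a freshly computed pre-activation tensor.

    ``z`` is consumed.  Returns the output and a cache (positive mask,
    lambda*alpha*expm1 of the negative part) from which the backward pass
    rebuilds the derivative without re-evaluating exp — the activations sit
    on the training hot path and are memory-bound.
    """
    pos = z > 0
    e = np.minimum(z, 0)
    np.expm1(e, out=e)
    e *= DTYPE(SELU_LAMBDA * SELU_ALPHA)  # e = lambda*alpha*(exp(z)-1) for z<=0
    z *= DTYPE(SELU_LAMBDA)
    np.copyto(z, e, where=~pos)
    return z, (pos, e)


def _selu_backward(d: np.ndarray, cache: tuple) -> np.ndarray:
    pos, e = cache
    g = e + DTYPE(SELU_LAMBDA * SELU_ALPHA)  # lambda*alpha*exp(z) on the negative side
    np.copyto(g, DTYPE(SELU_LAMBDA), where=pos)
    g *= d
    return g


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    """Affine map with optional SELU activation; LeCun-normal init."""

    def __init__(self, d_in: int, d_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "selu":
            out, self._act = _selu_forward(z)
            return out
        return z

    def backward(self, d):
        if self.activation == "selu":
            d = _selu_backward(d, self._act)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = d.reshape(-1, d.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return d @ self.W.value.T


class Conv1D(Layer):
    """'valid' 1-D convolution over (batch, time, channels), SELU optional."""

    def __init__(self, c_in: int, c_out: int, kernel: int, activation: str | None = "selu",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(kernel * c_in), (kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        K = self.kernel
        To = x.shape[1] - K + 1
        z = np.broadcast_to(self.b.value, (x.shape[0], To, self.b.value.size)).copy()
        for k in range(K):
            z += x[:, k : k + To, :] @ self.W.value[k]
        if self.activation == "selu":
            out, self._act = _selu_forward(z)
            return out
        return z

    def backward(self, d):
        if self.activation == "selu":
            d = _selu_backward(d, self._act)
        x = self._x
        K = self.kernel
        To = d.shape[1]
        dx = np.zeros_like(x)
        d2 = d.reshape(-1, d.shape[-1])
        for k in range(K):
            xk = x[:, k : k + To, :]
            self.W.grad[k] += xk.reshape(-1, xk.shape[-1]).T @ d2
            dx[:, k : k + To, :] += d @ self.W.value[k].T
        self.b.grad += d2.sum(axis=0)
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time (trailing remainder dropped)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x):
        s = self.size
        Tp = x.shape[1] // s
        xr = x[:, : Tp * s, :].reshape(x.shape[0], Tp, s, x.shape[2])
        self._idx = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, d):
        B, Tp, C = d.shape
        s = self.size
        dxr = np.zeros((B, Tp, s, C), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[:, :, None, :], d[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, : Tp * s, :] = dxr.reshape(B, Tp * s, C)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, rng: np.random.Generator | None = None, train: bool = False):
        if not train or self.rate == 0 or rng is None:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


class LayerNorm(Layer):
    """Normalise over the trailing feature axis with learnable gain/bias."""

    def __init__(self, d: int, eps: float = 1e-3):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return (self.gamma.value * self._xhat + self.beta.value).astype(DTYPE)

    def backward(self, d):
        xhat, inv = self._xhat, self._inv
        D = xhat.shape[-1]
        axes = tuple(range(xhat.ndim - 1))
        self.gamma.grad += (d * xhat).sum(axis=axes)
        self.beta.grad += d.sum(axis=axes)
        dxhat = d * self.gamma.value
        return (
            inv / D * (D * dxhat - dxhat.sum(-1, keepdims=True)
                       - xhat * (dxhat * xhat).sum(-1, keepdims=True))
        ).astype(DTYPE)


class GroupedConv1D(Layer):
    """Per-group 'valid' 1-D convolution over (groups, batch, time, features).

    One weight tensor (G, K, f_in, f_out) holds G independent convolutions
    evaluated as K stacked matmuls — the workhorse of the per-channel
    ConvNet branches, which would otherwise cost hundreds of tiny matmuls.
    """

    def __init__(self, groups: int, c_in: int, c_out: int, kernel: int,
                 activation: str | None = "selu", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(kernel * c_in), (groups, kernel, c_in, c_out)))
        self.b = Param(np.zeros((groups, c_out)))
        self.kernel = kernel
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        G, B, T, F = x.shape
        K = self.kernel
        To = T - K + 1
        self._in_shape = x.shape
        # im2col: (G, B, To, K, F) -> (G, B*To, K*F); ordering matches W.reshape
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)  # (G,B,To,F,K)
        xcol = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3)).reshape(G, B * To, K * F)
        self._xcol = xcol
        Wc = self.W.value.reshape(G, K * F, -1)
        z = (xcol @ Wc).reshape(G, B, To, -1) + self.b.value[:, None, None, :]
        if self.activation == "selu":
            out, self._act = _selu_forward(z)
            return out
        return z

    def backward(self, d):
        if self.activation == "selu":
            d = _selu_backward(d, self._act)
        G, B, T, F = self._in_shape
        K = self.kernel
        To = d.shape[2]
        d2 = np.ascontiguousarray(d).reshape(G, B * To, -1)
        self.b.grad += d2.sum(axis=1)
        Wc = self.W.value.reshape(G, K * F, -1)
        self.W.grad += (self._xcol.transpose(0, 2, 1) @ d2).reshape(self.W.grad.shape)
        dxcol = (d2 @ Wc.transpose(0, 2, 1)).reshape(G, B, To, K, F)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for k in range(K):
            dx[:, :, k : k + To, :] += dxcol[:, :, :, k, :]
        return dx


class GroupedMaxPool1D(Layer):
    """Non-overlapping max pooling along the time axis of (G, B, T, F).

    Size 2 (the only size the classifiers use) is special-cased as a single
    pairwise compare, avoiding an argmax pass."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x):
        s = self.size
        G, B, T, F = x.shape
        Tp = T // s
        self._in_shape = x.shape
        xr = x[:, :, : Tp * s, :].reshape(G, B, Tp, s, F)
        if s == 2:
            a, b = xr[:, :, :, 0, :], xr[:, :, :, 1, :]
            self._right = b > a
            return np.where(self._right, b, a)
        self._idx = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, d):
        G, B, Tp, F = d.shape
        s = self.size
        dxr = np.zeros((G, B, Tp, s, F), dtype=DTYPE)
        if s == 2:
            np.copyto(dxr[:, :, :, 1, :], d, where=self._right)
            np.copyto(dxr[:, :, :, 0, :], d, where=~self._right)
        else:
            np.put_along_axis(dxr, self._idx[:, :, :, None, :], d[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, :, : Tp * s, :] = dxr.reshape(G, B, Tp * s, F)
        return dx


class GroupedDense(Layer):
    """Per-group affine map: (G, B, d_in) @ (G, d_in, d_out) + (G, 1, d_out)."""

    def __init__(self, groups: int, d_in: int, d_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(d_in), (groups, d_in, d_out)))
        self.b = Param(np.zeros((groups, d_out)))
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        z = x @ self.W.value + self.b.value[:, None, :]
        if self.activation == "selu":
            out, self._act = _selu_forward(z)
            return out
        return z

    def backward(self, d):
        if self.activation == "selu":
            d = _selu_backward(d, self._act)
        self.W.grad += self._x.transpose(0, 2, 1) @ d
        self.b.grad += d.sum(axis=1)
        return d @ self.W.value.transpose(0, 2, 1)


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Standard scaled-dot-product self-attention over (batch, tokens, d_model).

    Queries/keys/values are projected to ``heads * key_dim`` and the context
    is projected back to ``d_model``.  Dropout acts on the attention weights.
    The last attention map is kept on the instance for inspection.
    """

    def __init__(self, d_model: int, heads: int, key_dim: int, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        h = heads * key_dim
        init = lambda di, do: rng.normal(0.0, 1.0 / np.sqrt(di), (di, do))
        self.Wq, self.Wk, self.Wv = (Param(init(d_model, h)) for _ in range(3))
        self.bq, self.bk, self.bv = (Param(np.zeros(h)) for _ in range(3))
        self.Wo, self.bo = Param(init(h, d_model)), Param(np.zeros(d_model))
        self.heads, self.key_dim = heads, key_dim
        self.drop = Dropout(dropout)
        self.last_attention: np.ndarray | None = None

    def params(self):
        return [self.Wq, self.bq, self.Wk, self.bk, self.Wv, self.bv, self.Wo, self.bo]

    def _split(self, z, B, T):
        return z.reshape(B, T, self.heads, self.key_dim).transpose(0, 2, 1, 3)

    def forward(self, x, rng=None, train=False):
        B, T, _ = x.shape
        self._x = x
        Q = self._split(x @ self.Wq.value + self.bq.value, B, T)
        K = self._split(x @ self.Wk.value + self.bk.value, B, T)
        V = self._split(x @ self.Wv.value + self.bv.value, B, T)
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.key_dim)
        A = _softmax(scores).astype(DTYPE)
        Ad = self.drop.forward(A, rng, train)
        ctx = Ad @ V  # (B, H, T, dk)
        ctx_flat = ctx.transpose(0, 2, 1, 3).reshape(B, T, -1)
        self._cache = (Q, K, V, A, Ad, ctx_flat)
        self.last_attention = A
        return ctx_flat @ self.Wo.value + self.bo.value

    def backward(self, d):
        Q, K, V, A, Ad, ctx_flat = self._cache
        x = self._x
        B, T, _ = x.shape
        d2 = d.reshape(-1, d.shape[-1])
        self.Wo.grad += ctx_flat.reshape(-1, ctx_flat.shape[-1]).T @ d2
        self.bo.grad += d2.sum(axis=0)
        dctx = (d @ self.Wo.value.T).reshape(B, T, self.heads, self.key_dim).transpose(0, 2, 1, 3)
        dAd = dctx @ V.transpose(0, 1, 3, 2)
        dV = Ad.transpose(0, 1, 3, 2) @ dctx
        dA = self.drop.backward(dAd)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True)) / np.sqrt(self.key_dim)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dx = np.zeros_like(x)
        x2 = x.reshape(-1, x.shape[-1])
        for dz, W, b in ((dQ, self.Wq, self.bq), (dK, self.Wk, self.bk), (dV, self.Wv, self.bv)):
            dz_flat = dz.transpose(0, 2, 1, 3).reshape(B * T, -1)
            W.grad += x2.T @ dz_flat
            b.grad += dz_flat.sum(axis=0)
            dx += (dz_flat @ W.value.T).reshape(B, T, -1)
        return dx


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = _softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    d = probs
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(DTYPE)


class Nadam:
    """Nesterov-accelerated Adam (Dozat 2016) with bias correction."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** (t + 1))
            v_hat = v / (1 - b2 ** t)
            update = (b1 * m_hat + (1 - b1) * g / (1 - b1 ** t)) / (np.sqrt(v_hat) + self.eps)
            p.value -= self.lr * update
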