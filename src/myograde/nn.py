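"""Minimal NumPy neural-network layers with explicit reverse-mode gradients.

Every layer implements ``forward(x, train)`` and ``backward(dy)``; ``backward``
accumulates parameter gradients in-place and returns the gradient with respect
to the layer input.  All randomness (initialisation, dropout masks, shuffling)
is drawn from ``numpy.random.Generator`` objects supplied by the caller, so a
single integer seed makes whole training runs reproducible.

The layer set is deliberately small: exactly what the strength-grading model
needs (dilated 1-D convolution, batch norm, average pooling, multi-head
attention, dense layers, dropout) plus an Adam optimiser.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv1dSame",
    "BatchNorm1d",
    "ReLU",
    "AvgPool1d",
    "Dropout",
    "Flatten",
    "Transpose",
    "MultiHeadAttention",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "count_parameters",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = True
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def count_parameters(obj) -> int:
    """Sum of element counts of all *trainable* parameters of a layer/model."""
    return sum(p.size for p in obj.params() if p.trainable)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _xavier_init(rng: np.random.Generator, shape, fan_in: int,
                 fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Dense(Layer):
    """Affine map on the last axis; accepts (B, d_in) or (B, T, d_in) input.

    ``init="he"`` (default) suits ReLU-followed layers; ``init="xavier"``
    keeps output layers un-saturated at the start of training.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "dense",
                 init: str = "he") -> None:
        if init == "he":
            W0 = _he_init(rng, (d_in, d_out), d_in)
        elif init == "xavier":
            W0 = _xavier_init(rng, (d_in, d_out), d_in, d_out)
        elif init == "small":
            # near-zero logit layer: softmax starts at the uniform distribution
            W0 = rng.normal(0.0, 1e-2, (d_in, d_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = Param(W0, name=f"{name}.W")
        self.b = Param(np.zeros(d_out), name=f"{name}.b") if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x = self._x
        # collapse leading axes for the weight gradient
        xf = x.reshape(-1, x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        if self.W.trainable:
            self.W.grad += xf.T @ dyf
        if self.b is not None and self.b.trainable:
            self.b.grad += dyf.sum(axis=0)
        return dy @ self.W.value.T


class Conv1dSame(Layer):
    """Dilated 1-D convolution with 'same' zero padding, input (B, C, T).

    Odd kernels only, so the padding is symmetric and the output length equals
    the input length.  Bias-free by default (a following batch norm supplies
    the shift).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator, bias: bool = False,
                 name: str = "conv") -> None:
        if kernel % 2 == 0:
            raise ValueError("Conv1dSame requires an odd kernel size")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.dilation = kernel, dilation
        self.W = Param(_he_init(rng, (c_out, c_in, kernel), c_in * kernel),
                       name=f"{name}.W")
        self.b = Param(np.zeros(c_out), name=f"{name}.b") if bias else None
        self._xpad = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def forward(self, x, train=False):
        B, C, T = x.shape
        p = self.pad
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._xpad = xpad
        self._T = T
        y = np.zeros((B, self.c_out, T))
        for j in range(self.kernel):
            off = j * self.dilation
            # (c_out, c_in) @ (B, c_in, T) tap slice
            y += np.einsum("oc,bct->bot", self.W.value[:, :, j],
                           xpad[:, :, off:off + T], optimize=True)
        if self.b is not None:
            y += self.b.value[None, :, None]
        return y

    def backward(self, dy):
        T, p = self._T, self.pad
        xpad = self._xpad
        dxpad = np.zeros_like(xpad)
        for j in range(self.kernel):
            off = j * self.dilation
            xs = xpad[:, :, off:off + T]
            if self.W.trainable:
                self.W.grad[:, :, j] += np.einsum("bot,bct->oc", dy, xs,
                                                  optimize=True)
            dxpad[:, :, off:off + T] += np.einsum(
                "oc,bot->bct", self.W.value[:, :, j], dy, optimize=True)
        if self.b is not None and self.b.trainable:
            self.b.grad += dy.sum(axis=(0, 2))
        return dxpad[:, :, p:p + T]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (B, C, T), statistics over (B, T)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        B, C, T = shape
        if self.gamma.trainable:
            self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        if self.beta.trainable:
            self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        if not train:
            return dxhat * inv[None, :, None]
        n = B * T
        # standard batch-norm backward, statistics taken over (B, T)
        term = (dxhat
                - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True))
        del n
        return term * inv[None, :, None]


class FeatureNorm(Layer):
    """Non-affine batch normalisation of a (B, D) feature matrix.

    Standardizes each feature over the batch (running statistics in eval
    mode).  Carries no trainable parameters; used purely to condition the
    input of the dense head.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return xhat

    def backward(self, dy):
        xhat, inv, train = self._cache
        if not train:
            return dy * inv
        term = (dy - dy.mean(axis=0) - xhat * (dy * xhat).mean(axis=0))
        return term * inv


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool1d(Layer):
    """Average pooling along time, input (B, C, T)."""

    def __init__(self, kernel: int, stride: int | None = None) -> None:
        self.kernel = kernel
        self.stride = kernel if stride is None else stride

    def forward(self, x, train=False):
        B, C, T = x.shape
        k, s = self.kernel, self.stride
        n_out = (T - k) // s + 1
        self._shape = x.shape
        out = np.empty((B, C, n_out))
        for i in range(n_out):
            out[:, :, i] = x[:, :, i * s:i * s + k].mean(axis=2)
        return out

    def backward(self, dy):
        B, C, T = self._shape
        k, s = self.kernel, self.stride
        dx = np.zeros(self._shape)
        for i in range(dy.shape[2]):
            dx[:, :, i * s:i * s + k] += dy[:, :, i][:, :, None] / k
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Transpose(Layer):
    """(B, C, T) <-> (B, T, C)."""

    def forward(self, x, train=False):
        return np.ascontiguousarray(np.swapaxes(x, 1, 2))

    def backward(self, dy):
        return np.ascontiguousarray(np.swapaxes(dy, 1, 2))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Layer):
    """Scaled dot-product attention with per-head Q/K/V maps and an output mix.

    Input (B, T, d_in).  Per head h: Q = X Wq[h], K = X Wk[h], V = X Wv[h];
    A = softmax(Q K^T / scale); head output A V.  Heads are concatenated and
    mixed by Wo into d_out per token.  ``scale`` is a fixed constant, not
    sqrt(d_k): the grading model divides by the raw segment length.
    Projections are bias-free.
    """

    def __init__(self, d_in: int, n_heads: int, d_k: int, d_v: int,
                 d_out: int, scale: float, rng: np.random.Generator,
                 name: str = "mha") -> None:
        self.n_heads, self.d_k, self.d_v = n_heads, d_k, d_v
        self.scale = float(scale)
        # variance-corrected query/key init: the score divisor can be much
        # larger than sqrt(d_k) (it is the raw segment length here), which
        # would flatten the softmax to uniform and collapse every token to
        # the token mean; choose Wq/Wk spread so Q K^T / scale has O(1)
        # entries at initialisation.
        s_qk = np.sqrt(self.scale) / (d_k ** 0.25 * np.sqrt(d_in))
        self.Wq = Param(rng.normal(0.0, s_qk, (n_heads, d_in, d_k)),
                        name=f"{name}.Wq")
        self.Wk = Param(rng.normal(0.0, s_qk, (n_heads, d_in, d_k)),
                        name=f"{name}.Wk")
        self.Wv = Param(_he_init(rng, (n_heads, d_in, d_v), d_in), name=f"{name}.Wv")
        self.Wo = Param(_he_init(rng, (n_heads * d_v, d_out), n_heads * d_v),
                        name=f"{name}.Wo")

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Return the (B, heads, T, T) softmax attention matrices for input x."""
        Q = np.einsum("btd,hdk->bhtk", x, self.Wq.value, optimize=True)
        K = np.einsum("btd,hdk->bhtk", x, self.Wk.value, optimize=True)
        S = np.einsum("bhtk,bhsk->bhts", Q, K, optimize=True) / self.scale
        return softmax(S, axis=-1)

    def forward(self, x, train=False):
        B, T, d = x.shape
        Q = np.einsum("btd,hdk->bhtk", x, self.Wq.value, optimize=True)
        K = np.einsum("btd,hdk->bhtk", x, self.Wk.value, optimize=True)
        V = np.einsum("btd,hdv->bhtv", x, self.Wv.value, optimize=True)
        S = np.einsum("bhtk,bhsk->bhts", Q, K, optimize=True) / self.scale
        A = softmax(S, axis=-1)
        H = np.einsum("bhts,bhsv->bhtv", A, V, optimize=True)
        # concat heads: (B, T, h*d_v)
        C = np.transpose(H, (0, 2, 1, 3)).reshape(B, T, self.n_heads * self.d_v)
        y = C @ self.Wo.value
        self._cache = (x, Q, K, V, A, C)
        return y

    def backward(self, dy):
        x, Q, K, V, A, C = self._cache
        B, T, d = x.shape
        h, dk, dv = self.n_heads, self.d_k, self.d_v
        if self.Wo.trainable:
            self.Wo.grad += C.reshape(-1, h * dv).T @ dy.reshape(-1, dy.shape[-1])
        dC = dy @ self.Wo.value.T
        dH = np.transpose(dC.reshape(B, T, h, dv), (0, 2, 1, 3))
        dA = np.einsum("bhtv,bhsv->bhts", dH, V, optimize=True)
        dV = np.einsum("bhts,bhtv->bhsv", A, dH, optimize=True)
        # softmax backward row-wise
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= self.scale
        dQ = np.einsum("bhts,bhsk->bhtk", dS, K, optimize=True)
        dK = np.einsum("bhts,bhtk->bhsk", dS, Q, optimize=True)
        if self.Wq.trainable:
            self.Wq.grad += np.einsum("btd,bhtk->hdk", x, dQ, optimize=True)
        if self.Wk.trainable:
            self.Wk.grad += np.einsum("btd,bhtk->hdk", x, dK, optimize=True)
        if self.Wv.trainable:
            self.Wv.grad += np.einsum("btd,bhtv->hdv", x, dV, optimize=True)
        dx = (np.einsum("bhtk,hdk->btd", dQ, self.Wq.value, optimize=True)
              + np.einsum("bhtk,hdk->btd", dK, self.Wk.value, optimize=True)
              + np.einsum("bhtv,hdv->btd", dV, self.Wv.value, optimize=True))
        return dx


class TransformerBlock(Layer):
    """Multi-head attention with residual connection and a 2-layer FFN.

    y = FFN(x + MHA(x)); the attention output mix W^O maps back to the token
    dimension so the residual is well-defined, and the position-wise
    feed-forward net (d_token -> ffn_hidden -> d_out, ReLU, bias-free) maps
    each token to its output width.
    """

    def __init__(self, d_token: int, n_heads: int, d_k: int, d_v: int,
                 ffn_hidden: int, d_out: int, scale: float,
                 rng: np.random.Generator, name: str = "tblock") -> None:
        self.mha = MultiHeadAttention(d_token, n_heads, d_k, d_v, d_token,
                                      scale, rng, name=f"{name}.mha")
        self.ffn1 = Dense(d_token, ffn_hidden, rng, bias=False,
                          name=f"{name}.ffn1")
        self.ffn_relu = ReLU()
        self.ffn2 = Dense(ffn_hidden, d_out, rng, bias=False,
                          name=f"{name}.ffn2")

    def params(self):
        return self.mha.params() + self.ffn1.params() + self.ffn2.params()

    def forward(self, x, train=False):
        h = x + self.mha.forward(x, train)
        h = self.ffn_relu.forward(self.ffn1.forward(h, train), train)
        return self.ffn2.forward(h, train)

    def backward(self, dy):
        dh = self.ffn1.backward(self.ffn_relu.backward(self.ffn2.backward(dy)))
        return dh + self.mha.backward(dh)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  eps: float = 1e-12) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the *logits*.

    ``probs`` must already be softmax outputs; the returned gradient is the
    usual (p - onehot)/B shortcut valid when backpropagating through the
    softmax that produced ``probs``.
    """
    B, K = probs.shape
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), labels] = 1.0
    loss = -np.mean(np.log(probs[np.arange(B), labels] + eps))
    grad = (probs - onehot) / B
    return loss, grad


class SGD:
    """Plain gradient descent; steps stay proportional to the gradient.

    Used where Adam's per-parameter normalisation is undesirable (e.g.
    cluster centres under a weak clustering loss, where scale-free steps
    would amplify gradient noise into drift).
    """

    def __init__(self, params: list[Param], lr: float) -> None:
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p in self.params:
            if p.trainable:
                p.value -= self.lr * p.grad


class Adam:
    """Adam optimiser over a list of Params; frozen params are skipped."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
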