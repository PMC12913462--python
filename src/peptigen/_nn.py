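"""Minimal seeded neural-network engine (dense + 1-D conv, Adam, softmax CE).

Everything is plain numpy with explicit backprop.  Design matrices may be
scipy sparse for the dense input layer.  All randomness (init, shuffling,
dropout) flows from a single ``numpy.random.Generator`` so training is
bit-reproducible for a fixed seed and thread-independent.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _matmul(x, w):
    # scipy sparse @ ndarray returns ndarray
    return x @ w


class Dense:
    """Affine layer y = xW + b with He-style init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * limit
        self.b = np.zeros(n_out)
        self._x = None

    def forward(self, x):
        self._x = x
        return _matmul(x, self.W) + self.b

    def backward(self, grad):
        x = self._x
        self.dW = (x.T @ grad) if not sp.issparse(x) else np.asarray(x.T @ grad)
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout:
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, rng: np.random.Generator | None = None):
        if rng is None or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MultiWidthConv1d:
    """Parallel 1-D convolutions over the token axis with global max pooling.

    Input is a zero-padded tensor (n, T, d) with per-sample valid lengths.
    Each branch applies ``filters`` kernels of one width spanning the full
    embedding dimension, ReLU, then a max over valid window positions; the
    branch outputs are concatenated to (n, widths * filters).
    """

    def __init__(self, widths: list[int], filters: int, dim: int, rng: np.random.Generator):
        self.widths = list(widths)
        self.filters = filters
        self.dim = dim
        self.W = []
        self.b = []
        for w in self.widths:
            fan_in = w * dim
            self.W.append(rng.standard_normal((fan_in, filters)) * np.sqrt(2.0 / fan_in))
            self.b.append(np.zeros(filters))

    def forward(self, x: np.ndarray, lengths: np.ndarray):
        n, T, d = x.shape
        self._x_shape = x.shape
        self._cols = []
        self._argmax = []
        self._any_valid = []
        outs = []
        for wi, w in enumerate(self.widths):
            n_pos = T - w + 1
            if n_pos < 1:
                raise ValueError(f"sequence length {T} shorter than kernel width {w}")
            # im2col: (n, n_pos, w*d)
            windows = np.lib.stride_tricks.sliding_window_view(x, (w, d), axis=(1, 2))
            cols = windows.reshape(n, n_pos, w * d)
            act = cols @ self.W[wi] + self.b[wi]  # (n, n_pos, F)
            act = np.maximum(act, 0.0)
            valid = np.arange(n_pos)[None, :] + w <= lengths[:, None] + 0  # (n, n_pos)
            any_valid = valid.any(axis=1)
            masked = np.where(valid[:, :, None], act, -np.inf)
            arg = masked.argmax(axis=1)  # (n, F)
            pooled = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
            pooled = np.where(any_valid[:, None], pooled, 0.0)
            self._cols.append(cols)
            self._argmax.append(arg)
            self._any_valid.append(any_valid)
            outs.append(pooled)
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray):
        n, T, d = self._x_shape
        dx = np.zeros((n, T, d))
        self.dW = []
        self.db = []
        for wi, w in enumerate(self.widths):
            g = grad[:, wi * self.filters : (wi + 1) * self.filters].copy()
            g[~self._any_valid[wi]] = 0.0
            cols = self._cols[wi]
            arg = self._argmax[wi]  # (n, F) window index of each filter's max
            n_pos = cols.shape[1]
            # gradient flows only through the argmax window of each filter;
            # ReLU gate: pooled value > 0 iff pre-activation > 0 there
            sel = np.take_along_axis(
                cols[:, :, None, :], arg[:, None, :, None], axis=1
            )[:, 0]  # (n, F, w*d)
            pre = np.einsum("nfj,jf->nf", sel, self.W[wi]) + self.b[wi]
            g = g * (pre > 0)
            dW = np.einsum("nfj,nf->jf", sel, g)
            db = g.sum(axis=0)
            # scatter dx: for each sample/filter, add g * W column into window
            dcols = np.zeros_like(cols)
            contrib = g[:, :, None] * self.W[wi].T[None, :, :]  # (n, F, w*d)
            for f in range(self.filters):
                np.add.at(
                    dcols,
                    (np.arange(n), arg[:, f]),
                    contrib[:, f, :],
                )
            # fold columns back into (n, T, d)
            for p in range(n_pos):
                dx[:, p : p + w, :] += dcols[:, p, :].reshape(n, w, d)
            self.dW.append(dW)
            self.db.append(db)
        return dx

    def params(self):
        out = []
        for i in range(len(self.widths)):
            out.append((f"W{i}", self.W[i], self.dW[i]))
            out.append((f"b{i}", self.b[i], self.db[i]))
        return out

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss over the batch and the gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(targets)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[tuple[str, np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for i, (_, p, g) in enumerate(params):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def iterate_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
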