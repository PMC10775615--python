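"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the tensor, layer, and optimiser primitives that the
structure autoencoder and the cleavage classifiers are built from: dense and
1-D convolutional layers, batch normalisation, max pooling, dropout, the
sigmoid/softmax heads, and an Adam optimiser with L2-style weight decay.
Gradients are computed by backpropagation through a dynamically recorded
graph; correctness is established by finite-difference checks in the test
suite.

All arithmetic is float64. The models in this package are small (tens of
thousands of parameters, inputs of a few hundred elements), so clarity and
exactness are preferred over throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "Adam",
    "relu",
    "sigmoid",
    "softmax",
    "concat",
    "dropout",
    "maxpool1d",
    "mse_loss",
    "bce_loss",
    "weighted_nll_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def back(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * (other ** -1.0)
        return self * (1.0 / other)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = back
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = back
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def back(g):
            self._accumulate(g / self.data)

        out._backward = back
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def back(g):
            self._accumulate(g * out.data)

        out._backward = back
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Pick element `index[i]` from row i of a 2-D tensor."""
        rows = np.arange(self.data.shape[0])
        out = Tensor(self.data[rows, index], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, index), g)
            self._accumulate(full)

        out._backward = back
        return out


# -- nonlinearities and structural ops ------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def back(g):
        x._accumulate(g * (x.data > 0))

    out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def back(g):
        x._accumulate(g * s * (1.0 - s))

    out._backward = back
    return out


def softmax(x: Tensor) -> Tensor:
    """Row-wise softmax of a 2-D tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = Tensor(p, parents=(x,))

    def back(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accumulate(p * (g - dot))

    out._backward = back
    return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = back
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling along the last axis of a (B, C, W) tensor."""
    b, c, w = x.data.shape
    if w % k != 0:
        raise ValueError(f"width {w} not divisible by pool size {k}")
    windows = x.data.reshape(b, c, w // k, k)
    arg = windows.argmax(axis=3)
    out = Tensor(windows.max(axis=3), parents=(x,))

    def back(g):
        full = np.zeros_like(windows)
        bi, ci, wi = np.indices(arg.shape)
        full[bi, ci, wi, arg] = g
        x._accumulate(full.reshape(b, c, w))

    out._backward = back
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 'same' 1-D convolution: (B,C,W) * (F,C,K) -> (B,F,W).

    K must be odd so that symmetric zero padding preserves the width.
    """
    _, _, w = x.data.shape
    f, c, k = weight.data.shape
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,W,K)
    out_data = np.einsum("fck,bcwk->bfw", weight.data, cols) + bias.data[None, :, None]
    out = Tensor(out_data, parents=(x, weight, bias))

    def back(g):
        weight._accumulate(np.einsum("bfw,bcwk->fck", g, cols))
        bias._accumulate(g.sum(axis=(0, 2)))
        gcols = np.einsum("bfw,fck->bcwk", g, weight.data)
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[:, :, j:j + w] += gcols[:, :, :, j]
        x._accumulate(gxp[:, :, pad:pad + w])

    out._backward = back
    return out


# -- layers ----------------------------------------------------------------


class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list:
        """All arrays needed to restore the module (parameters + buffers)."""
        arrays: list[np.ndarray] = [p.data for p in self.parameters()]
        for m in self._submodules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list) -> None:
        params = self.parameters()
        n = len(params)
        bn = [m for m in self._submodules() if isinstance(m, BatchNorm1d)]
        expected = n + 2 * len(bn)
        if len(arrays) != expected:
            raise ValueError(f"expected {expected} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays[:n]):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64).copy()
        rest = arrays[n:]
        for i, m in enumerate(bn):
            m.running_mean = rest[2 * i].astype(np.float64).copy()
            m.running_var = rest[2 * i + 1].astype(np.float64).copy()

    def _submodules(self) -> list:
        subs: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                subs.extend(v._submodules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        subs.extend(item._submodules())
        return subs


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same-padding")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(
            rng.normal(0.0, scale, (c_out, c_in, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, width) of a (B,C,W) tensor."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones((1, channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1)), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma + self.beta


# -- losses ----------------------------------------------------------------

_EPS = 1e-12


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2.0).mean()


def bce_loss(prob: Tensor, target: np.ndarray) -> Tensor:
    """Binary cross entropy against probabilities in (0, 1)."""
    t = Tensor(np.asarray(target, dtype=np.float64))
    one = Tensor(np.ones_like(prob.data))
    loss = -(t * (prob + _EPS).log() + (one - t) * (one - prob + _EPS).log())
    return loss.mean()


def weighted_nll_loss(probs: Tensor, target: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Class-weighted negative log likelihood on (B, K) probabilities.

    Follows the weighted-mean convention: sum_i w[y_i] * -log p_i[y_i]
    divided by sum_i w[y_i], so setting every weight to 1 recovers the
    plain mean NLL.
    """
    target = np.asarray(target, dtype=np.int64)
    w = np.asarray(class_weights, dtype=np.float64)[target]
    picked = (probs + _EPS).log().gather_rows(target)
    return -(picked * Tensor(w)).sum() / float(w.sum())


# -- optimiser -------------------------------------------------------------


class Adam:
    """Adam with L2-style weight decay added to the gradient."""

    def __init__(self, params: list, lr: float = 0.001, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
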