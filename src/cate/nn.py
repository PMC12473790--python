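"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the package's numerical core: a tape-based scalar-loss autodiff
engine with exactly the operations the model needs (broadcast arithmetic,
batched matmul, exact-erf GELU, LayerNorm, softmax, cross-entropy), plus an
Adam optimizer, global-norm gradient clipping and a reduce-on-plateau
learning-rate schedule.  Everything is float64 and deterministic: no
threading, no in-place aliasing, all randomness passed in explicitly.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "matmul",
    "gelu",
    "layer_norm",
    "softmax",
    "cross_entropy_with_logits",
    "dropout",
    "Adam",
    "clip_grad_norm",
    "ReduceLROnPlateau",
]


class Tensor:
    """A NumPy array with a gradient tape.

    Arithmetic with plain arrays/scalars is supported; constants are wrapped
    on the fly and do not receive gradients unless ``requires_grad`` is set.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _vjp: Callable | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjp = _vjp

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this scalar into every parameter's .grad."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is not None:
                parent_grads = node._vjp(g)
                for p, pg in zip(node._parents, parent_grads):
                    if not p.requires_grad or pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            elif node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul(self, 1.0 / other)
        return mul(self, power(as_tensor(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(np.array(x, dtype=np.float64, copy=True), requires_grad=True)


# ----------------------------------------------------------------------
def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out_data, _parents=(a, b), _vjp=vjp)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def vjp(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out_data, _parents=(a, b), _vjp=vjp)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data**p

    def vjp(g):
        return (g * p * a.data ** (p - 1.0),)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def clip_min(a, lo: float) -> Tensor:
    """max(a, lo); gradient passes only where a > lo."""
    a = as_tensor(a)
    out_data = np.maximum(a.data, lo)

    def vjp(g):
        return (g * (a.data > lo),)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def vjp(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor(out_data, _parents=(a, b), _vjp=vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def vjp(g):
        return (g.reshape(a.data.shape),)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def vjp(g):
        return (g.transpose(inv),)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    """Exact (erf-form) Gaussian error linear unit."""
    a = as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))
    out_data = a.data * cdf

    def vjp(g):
        pdf = np.exp(-0.5 * a.data**2) * _INV_SQRT_2PI
        return (g * (cdf + a.data * pdf),)

    return Tensor(out_data, _parents=(a,), _vjp=vjp)


def layer_norm(a, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance (no affine)."""
    a = as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    n = a.data.shape[-1]

    def vjp(g):
        gm = g.mean(axis=-1, keepdims=True)
        gx = (g * xhat).mean(axis=-1, keepdims=True)
        return (inv * (g - gm - xhat * gx),)

    return Tensor(xhat, _parents=(a,), _vjp=vjp)


def softmax(a) -> Tensor:
    """Softmax over the last axis."""
    a = as_tensor(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def vjp(g):
        return (y * (g - (g * y).sum(axis=-1, keepdims=True)),)

    return Tensor(y, _parents=(a,), _vjp=vjp)


def cross_entropy_with_logits(logits, labels: np.ndarray) -> Tensor:
    """Mean negative log-softmax of the true class.

    ``labels`` is an integer vector; out-of-range labels raise.
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    B, K = logits.data.shape
    if labels.shape != (B,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {B}")
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError("label out of range for logit width")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    out = -logp[np.arange(B), labels].mean()

    def vjp(g):
        p = np.exp(logp)
        p[np.arange(B), labels] -= 1.0
        return (g * p / B,)

    return Tensor(out, _parents=(logits,), _vjp=vjp)


def dropout(a, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    a = as_tensor(a)
    if not training or rate == 0.0:
        return a
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def l2_normalize_rows(a, eps: float = 1e-24) -> Tensor:
    """Rows scaled to unit L2 norm; zero rows are left at zero via the eps guard."""
    n2 = tsum(power(a, 2.0), axis=-1, keepdims=True)
    return mul(a, power(clip_min(n2, eps), -0.5))


# ----------------------------------------------------------------------
# Optimisation utilities
# ----------------------------------------------------------------------
class Adam:
    """Adam with bias correction; operates on a list of parameter Tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g**2
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params: Iterable[Tensor], max_norm: float = 1.0) -> float:
    """Scale gradients by min(1, max_norm/||g||_2) over the global vector.

    Zero gradients pass through untouched (no 0/0). Returns the post-clip
    global norm.
    """
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        for p in params:
            p.grad = p.grad * scale
        return max_norm
    return total


class ReduceLROnPlateau:
    """Halve-on-stagnation learning-rate controller.

    After ``patience`` consecutive epochs without improvement of the
    monitored loss, the optimizer's lr is multiplied by ``factor`` and the
    bad-epoch counter resets.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = math.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Feed one epoch's monitored loss; returns True if lr was reduced."""
        if metric < self.best:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad > self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False
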