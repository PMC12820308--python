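"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32/float64 ndarray and records the operation
that produced it; :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the operations the diagnosis model needs are
implemented (broadcasting arithmetic, batched matmul, gather, reductions,
softmax building blocks, concat/reshape, a constant-sparse @ dense product)
plus an Adam optimizer.  Shapes follow numpy broadcasting; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        # `own=True` promises g is freshly allocated and never reused by the
        # caller, so it can be adopted without a defensive copy
        if self.grad is None:
            if own and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- arithmetic ---------------------------------------------------
    def __add__(self, other):
        # python scalars stay weak so float32 graphs are not promoted
        if isinstance(other, (int, float)):
            a, c = self, other

            def bw_s(g):
                if a.requires_grad:
                    a._accum(g, own=True)

            return Tensor._make(a.data + c, (a,), bw_s)
        a, b = self, Tensor._lift(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape), own=True)
            if b.requires_grad:
                gb = _unbroadcast(g, b.shape)
                b._accum(gb, own=gb is not g)

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g, own=True)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a, c = self, other

            def bw_s(g):
                if a.requires_grad:
                    a._accum(g * c, own=True)

            return Tensor._make(a.data * c, (a,), bw_s)
        a, b = self, Tensor._lift(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape), own=True)
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape), own=True)

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * Tensor._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        a = self
        out_data = a.data ** exponent

        def bw(g):
            if a.requires_grad:
                a._accum(g * exponent * a.data ** (exponent - 1.0), own=True)

        return Tensor._make(out_data, (a,), bw)

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data, own=True)

        return Tensor._make(out_data, (a,), bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(g / a.data, own=True)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bw(g):
            if a.requires_grad:
                a._accum(g * mask, own=True)

        return Tensor._make(a.data * mask, (a,), bw)

    # ---- linear algebra ----------------------------------------------
    def matmul(self, other) -> "Tensor":
        a, b = self, Tensor._lift(other)
        if a.ndim > 2 and b.ndim == 2:
            # flatten leading axes: one big GEMM instead of a batched loop,
            # and the weight gradient reduces without a huge intermediate
            k, n = b.shape
            a2 = a.data.reshape(-1, k)
            out = (a2 @ b.data).reshape(*a.shape[:-1], n)

            def bw_f(g):
                g2 = g.reshape(-1, n)
                if a.requires_grad:
                    a._accum((g2 @ b.data.T).reshape(a.shape), own=True)
                if b.requires_grad:
                    b._accum(a2.T @ g2, own=True)

            return Tensor._make(out, (a, b), bw_f)

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape), own=True)
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape), own=True)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    # ---- shape ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.shape

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(old), own=True)

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bw(g):
            if a.requires_grad:
                a._accum(g.transpose(*inv), own=True)

        return Tensor._make(a.data.transpose(*axes), (a,), bw)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (axis 0); backward scatter-adds via a sparse product."""
        a = self
        idx = np.asarray(indices)
        flat = idx.reshape(-1)

        def bw(g):
            if a.requires_grad:
                gf = g.reshape(len(flat), -1)
                scat = sp.csr_matrix(
                    (np.ones(len(flat), dtype=gf.dtype),
                     (flat, np.arange(len(flat)))),
                    shape=(a.shape[0], len(flat)),
                )
                a._accum((scat @ gf).reshape(a.shape), own=True)

        return Tensor._make(a.data[idx], (a,), bw)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy(), own=True)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy(), own=True)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- helpers -------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._parents))]
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
                    order.append(node)
                    stack.pop()

        visit(self)
        # clear stale intermediate grads so a subgraph shared between
        # successive backward calls cannot re-propagate old contributions
        for node in order:
            if node._backward is not None:
                node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    sizes = [p.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for p, gp in zip(parts, np.split(g, splits, axis=axis)):
            if p.requires_grad:
                p._accum(gp, own=True)

    return Tensor._make(
        np.concatenate([p.data for p in parts], axis=axis), parts, bw
    )


def spmm(a: sp.spmatrix, b: Tensor) -> Tensor:
    """Constant sparse matrix times dense tensor (grad flows to ``b``)."""
    bt = Tensor._lift(b)
    at = a.tocsr()

    def bw(g):
        if bt.requires_grad:
            bt._accum(at.T @ g, own=True)

    return Tensor._make(at @ bt.data, (bt,), bw)


def softmax(logits: Tensor, axis: int = -1,
            mask: Optional[np.ndarray] = None) -> Tensor:
    """Numerically stable softmax; ``mask`` (0/1 constant) excludes slots.

    Fully-masked rows come out all-zero rather than uniform.
    """
    x = logits
    if mask is not None:
        x = x + ((mask.astype(x.data.dtype) - 1.0) * 1e9)
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - shift).exp()
    if mask is not None:
        e = e * mask.astype(e.data.dtype)
    denom = e.sum(axis=axis, keepdims=True) + 1e-20
    return e / denom


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Per-row normalization over the last axis with a learnable affine."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps).pow(-0.5) * gamma + beta


def l2_normalize_rows(x: Tensor, eps: float = 1e-6) -> Tensor:
    # eps keeps the pow(-1.5) backward factor float32-safe for zero rows
    sq = (x * x).sum(axis=-1, keepdims=True)
    return x * (sq + eps).pow(-0.5)


def clip_global_norm(params: Sequence["Tensor"], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if not np.isfinite(norm):
        # drop the step rather than propagate inf/nan into the optimizer
        for p in params:
            if p.grad is not None:
                p.grad[...] = 0.0
        return norm
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """First-order adaptive gradient descent (Kingma & Ba defaults)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
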