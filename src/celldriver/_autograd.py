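"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the graph-attention encoder needs:
broadcast arithmetic, matmul, reductions, gather/scatter (for per-neighborhood
softmax on edge lists), and the pointwise nonlinearities (sigmoid, GELU,
softplus, abs, exp, log, sqrt).  Gradients flow through a topologically
sorted tape; broadcasting is undone by summing over expanded axes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr  # standard normal CDF, for exact GELU


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were expanded from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- pointwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,),
                          lambda g: (g * 0.5 / out_data,))

    def abs(self):
        return self._make(np.abs(self.data), (self,),
                          lambda g: (g * np.sign(self.data),))

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        return self._make(out_data, (self,),
                          lambda g: (g * out_data * (1.0 - out_data),))

    def gelu(self):
        """Exact GELU x*Phi(x); derivative Phi(x) + x*phi(x)."""
        phi_cdf = ndtr(self.data)
        out_data = self.data * phi_cdf

        def backward(g):
            pdf = np.exp(-0.5 * self.data ** 2) / np.sqrt(2.0 * np.pi)
            return (g * (phi_cdf + self.data * pdf),)

        return self._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + e^x), numerically stable; derivative sigmoid(x)."""
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))

        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
            return (g * sig,)

        return self._make(out_data, (self,), backward)

    # ---- shape / indexing ------------------------------------------------
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,),
                          lambda g: (g.reshape(self.data.shape),))

    def take_rows(self, idx: np.ndarray):
        """Gather rows (axis 0); gradient scatter-adds back."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(out_data, (self,), backward)

    def scatter_add_rows(self, idx: np.ndarray, n_rows: int):
        """Scatter rows of self into a zero array of n_rows rows, summing
        duplicates; gradient gathers."""
        idx = np.asarray(idx)
        out_shape = (n_rows,) + self.data.shape[1:]
        out_data = np.zeros(out_shape)
        np.add.at(out_data, idx, self.data)
        return self._make(out_data, (self,), lambda g: (g[idx],))


def spmm(s, x: Tensor) -> Tensor:
    """Constant sparse matrix times Tensor (2-D); used for gather rows
    (selection matrix) and segment scatter-add (its transpose)."""
    out_data = s @ x.data
    st = s.T.tocsr()
    return Tensor._make(out_data, (x,), lambda g: (st @ g,))


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def segment_softmax(scores: Tensor, segments: np.ndarray, n_segments: int,
                    tau: float) -> Tensor:
    """Softmax of scores/tau within each segment (per-neighborhood
    normalization), with detached max-subtraction for stability.
    Works on (P,) or (P, K) scores with segments along axis 0."""
    s = scores * (1.0 / tau)
    shape = (n_segments,) + s.data.shape[1:]
    seg_max = np.full(shape, -np.inf)
    np.maximum.at(seg_max, segments, s.data)
    z = (s - Tensor(seg_max[segments])).exp()
    denom = z.scatter_add_rows(segments, n_segments)
    return z / denom.take_rows(segments)


def backward(loss: Tensor):
    """Accumulate gradients of `loss` (scalar) into every reachable tensor
    with requires_grad."""
    topo: list[Tensor] = []
    seen = set()
    stack = [(loss, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    grads: dict[int, np.ndarray] = {id(loss): np.ones_like(loss.data)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node._backward is not None:
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg.copy() if isinstance(pg, np.ndarray) else np.asarray(pg, dtype=float)
        else:  # leaf parameter
            node.grad = g if node.grad is None else node.grad + g


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
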