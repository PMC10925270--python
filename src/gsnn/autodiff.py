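"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute core used by the GSNN model, the baseline multilayer
perceptron, the edge-mask explainer and the Beta-likelihood viability head.
It implements exactly the primitives those models need — dense and sparse
linear maps, segment reductions for per-node normalization, elementwise
nonlinearities, and log-gamma for Beta likelihoods — with gradients
accumulated over a dynamically recorded tape.

Conventions: tensors wrap ``float64`` numpy arrays; broadcasting follows
numpy semantics and gradients of broadcast operands are summed back to the
operand shape.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln

__all__ = ["Tensor", "Adam", "sparse_linear", "right_spmm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting added or stretched."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                # leaf
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g, a.data.shape)),
                    (b, _unbroadcast(g, b.data.shape)))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g * b.data, a.data.shape)),
                    (b, _unbroadcast(g * a.data, b.data.shape)))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return ((a, _unbroadcast(g / b.data, a.data.shape)),
                    (b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(a.data ** p, (a,),
                            lambda g: ((a, g * p * a.data ** (p - 1)),))

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return ((a, g @ b.data.T), (b, a.data.T @ g))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * 0.5 / out_data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * (1 - out_data ** 2)),))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,),
                            lambda g: ((a, g * out_data * (1 - out_data)),))

    def softplus(self):
        a = self
        # numerically stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        out_data = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
        sig = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: ((a, g * sig),))

    def elu(self):
        a = self
        neg = np.exp(np.minimum(a.data, 0.0)) - 1.0
        out_data = np.where(a.data > 0, a.data, neg)
        return Tensor._make(out_data, (a,),
                            lambda g: ((a, g * np.where(a.data > 0, 1.0, neg + 1.0)),))

    def relu(self):
        a = self
        return Tensor._make(np.maximum(a.data, 0.0), (a,),
                            lambda g: ((a, g * (a.data > 0)),))

    def lgamma(self):
        a = self
        return Tensor._make(gammaln(a.data), (a,),
                            lambda g: ((a, g * digamma(a.data)),))

    # ---------------------------------------------------------- array motion
    def take_cols(self, idx: np.ndarray):
        """Gather columns of a 2-D tensor: out[..., j] = self[..., idx[j]]."""
        a = self
        idx = np.asarray(idx)

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, (slice(None), idx), g)
            return ((a, full),)

        return Tensor._make(a.data[:, idx], (a,), bw)

    def put_cols(self, idx: np.ndarray, width: int):
        """Scatter a 2-D tensor into zero-padded columns of width `width`.

        idx must have no duplicates (each target column written once).
        """
        a = self
        idx = np.asarray(idx)
        out_data = np.zeros((a.data.shape[0], width))
        out_data[:, idx] = a.data
        return Tensor._make(out_data, (a,), lambda g: ((a, g[:, idx]),))


def right_spmm(x: Tensor, mat: sp.spmatrix) -> Tensor:
    """x @ mat.T for a *constant* sparse matrix `mat` of shape (out, in)."""
    a = x

    def bw(g):
        return ((a, mat.T.dot(g.T).T),)

    return Tensor._make(mat.dot(a.data.T).T, (a,), bw)


def sparse_linear(x: Tensor, w: Tensor, rows: np.ndarray, cols: np.ndarray,
                  shape: tuple) -> Tensor:
    """y = x @ W.T where W is sparse with trainable values `w` at (rows, cols).

    `shape` = (n_out, n_in); x is (batch, n_in); returns (batch, n_out).
    (rows, cols) must contain no duplicate pairs.
    """
    a, b = x, w
    mat = sp.csr_matrix((w.data, (rows, cols)), shape=shape)

    def bw(g):
        gx = mat.T.dot(g.T).T
        gw = (g[:, rows] * a.data[:, cols]).sum(axis=0)
        return ((a, gx), (b, gw))

    return Tensor._make(mat.dot(a.data.T).T, (a, b), bw)


class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
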