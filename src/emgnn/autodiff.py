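"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: (batched) dense matmul,
sparse-dense propagation, row gather/scatter, elementwise arithmetic and
activations, and reductions.  Leading batch dimensions broadcast through
every op, so a stack of interpolated inputs can be pushed through the
network in one pass (used by the integrated-gradients routines).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Adam", "concat", "log_softmax", "softmax", "spmm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _ensure(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._ensure(other))

    def __rsub__(self, other):
        return Tensor._ensure(other) + (-self)

    def __mul__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._ensure(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = backward
        return out

    # -- linear algebra -------------------------------------------------------

    def __matmul__(self, other):
        other = Tensor._ensure(other)
        if self.ndim == 1:
            out = self.reshape(1, -1) @ other
            return out.reshape(*out.shape[:-2], out.shape[-1])
        if other.ndim == 1:
            out = self @ other.reshape(-1, 1)
            return out.reshape(*out.shape[:-1])
        out = Tensor(
            np.matmul(self.data, other.data),
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- activations ----------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(
            np.where(mask, self.data, slope * self.data), self.requires_grad, (self,)
        )
        out._backward = lambda g: (np.where(mask, g, slope * g),)
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(orig),)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        orig = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, orig).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, orig).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def take_rows(self, idx):
        """Gather rows along the second-to-last axis."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(np.take(self.data, idx, axis=-2), self.requires_grad, (self,))
        nrows = self.shape[-2]
        unique = len(np.unique(idx)) == len(idx)

        def backward(g):
            full = np.zeros(g.shape[:-2] + (nrows, g.shape[-1]), dtype=g.dtype)
            if unique:  # plain assignment; add.at is far slower
                full[..., idx, :] = g
            else:
                np.add.at(full, (..., idx, slice(None)), g)
            return (full,)

        out._backward = backward
        return out

    def scatter_rows(self, idx, n_rows: int):
        """Scatter-add rows into a zero tensor of `n_rows` rows (axis -2)."""
        idx = np.asarray(idx, dtype=np.intp)
        shape = self.shape[:-2] + (n_rows, self.shape[-1])
        data = np.zeros(shape, dtype=self.data.dtype)
        if len(np.unique(idx)) == len(idx):
            data[..., idx, :] = self.data
        else:
            np.add.at(data, (..., idx, slice(None)), self.data)
        out = Tensor(data, self.requires_grad, (self,))
        out._backward = lambda g: (np.take(g, idx, axis=-2),)
        return out

    def take_last(self, idx):
        """Gather along the last axis (used for per-edge weight lookup)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(np.take(self.data, idx, axis=-1), self.requires_grad, (self,))
        n = self.shape[-1]

        def backward(g):
            full = np.zeros(g.shape[:-1] + (n,), dtype=g.dtype)
            np.add.at(full, (..., idx), g)
            return (full,)

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
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
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # the root may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse @ dense with an optional leading batch dimension on `x`."""
    x = Tensor._ensure(x)
    csr = matrix.tocsr()

    def apply(m, arr):
        if arr.ndim == 2:
            return m @ arr
        b, n, h = arr.shape
        flat = np.ascontiguousarray(np.moveaxis(arr, 1, 0)).reshape(n, b * h)
        return np.moveaxis((m @ flat).reshape(n, b, h), 0, 1)

    out = Tensor(apply(csr, x.data), x.requires_grad, (x,))
    csr_t = csr.T.tocsr()
    out._backward = lambda g: (apply(csr_t, g),)
    return out


def concat(tensors, axis: int = -2) -> Tensor:
    tensors = [Tensor._ensure(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the detached max leaves both value and gradient unchanged
    shifted = x - x.data.max(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay on gradients."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
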