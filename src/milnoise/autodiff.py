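"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the MIL aggregators need: broadcast
arithmetic, (batched) matmul, elementwise nonlinearities, softmax/log-sum-exp
building blocks, reductions, reshapes, concatenation, and fancy indexing.
Gradients flow through a dynamically built tape; ``Tensor.backward`` runs a
topological sweep. Everything is float64 and single-threaded, which keeps
training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
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
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> np.ndarray:
        return self.data

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))
        return self._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)
        return self._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))
        return self._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))
        return self._node(self.data / other.data, (self, other), bwd)

    def __pow__(self, exponent: float):
        def bwd(g, a=self, e=exponent):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1))
        return self._node(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))
        return self._node(self.data @ other.data, (self, other), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g * o)
        return self._node(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)
        return self._node(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g * (1.0 - o**2))
        return self._node(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g * o * (1.0 - o))
        return self._node(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0
        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)
        return self._node(self.data * mask, (self,), bwd)

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bwd(g, a=self, s=sig):
            if a.requires_grad:
                a._accumulate(g * s)
        return self._node(out_data, (self,), bwd)

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape).copy())
        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(g.reshape(a.shape))
        return self._node(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, axes):
        inverse = np.argsort(axes)
        def bwd(g, a=self, inv=inverse):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))
        return self._node(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, index):
        def bwd(g, a=self, ix=index):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, ix, g)
                a._accumulate(full)
        return self._node(self.data[index], (self,), bwd)

    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        c = self.data.max(axis=axis, keepdims=True)
        out = (self - c).exp().sum(axis=axis, keepdims=True).log() + c
        if not keepdims:
            out = out.reshape(*np.sum(out.data, axis=axis).shape)
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g, ts=tensors, offs=offsets, ax=axis):
        for t, start, stop in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(start, stop)
                t._accumulate(g[tuple(sl)])
    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._node(data, tuple(tensors), bwd)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
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
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
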