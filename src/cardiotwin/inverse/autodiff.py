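"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the dual-branch VAE needs: broadcasted
arithmetic, (batched) matmul, tanh/relu/exp/log, reductions, max-pooling,
reshape/transpose/concat/slice, repeat, and fused softmax cross-entropy.
Gradients are accumulated in float64; graphs are built dynamically and
freed after ``backward``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    for _ in range(nd):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = parents

    # -- graph --------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        o = self._lift(other)
        out = Tensor(self.data + o.data, True, (self, o))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)
        out = Tensor(self.data * o.data, True, (self, o))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        out = Tensor(self.data / o.data, True, (self, o))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / o.data ** 2, o.data.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1))
        return out

    def matmul(self, other):
        o = self._lift(other)
        out = Tensor(self.data @ o.data, True, (self, o))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accum(_unbroadcast(gb, o.data.shape))
        out._backward = bw
        return out

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - y ** 2))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (self.data > 0))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    # -- reductions & shaping -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        y = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(y, True, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis),
                              np.broadcast_to(gg, np.expand_dims(idx, axis).shape),
                              axis=axis)
            self._accum(grad)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), True, (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(*inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], True, (self,))

        def bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accum(grad)
        out._backward = bw
        return out

    def repeat(self, reps: int, axis: int):
        """np.repeat along an axis (gradient sums the repeats)."""
        out = Tensor(np.repeat(self.data, reps, axis=axis), True, (self,))

        def bw(g):
            if self.requires_grad:
                shp = list(self.data.shape)
                shp.insert(axis + 1, reps)
                self._accum(g.reshape(shp).sum(axis=axis + 1))
        out._backward = bw
        return out


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), True, tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    m = np.max(t.data, axis=axis, keepdims=True)
    e = (t - Tensor(m)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` (..., C), integer targets."""
    x = logits.data
    m = x.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))
    tg = np.asarray(targets, dtype=int)
    picked = np.take_along_axis(x, tg[..., None], axis=-1)[..., 0]
    n = tg.size
    out = Tensor((lse[..., 0] - picked).sum() / n, True, (logits,))

    def bw(g):
        if logits.requires_grad:
            p = np.exp(x - lse)
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, tg[..., None], 1.0, axis=-1)
            logits._accum(g * (p - onehot) / n)
    out._backward = bw
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, *shape) -> Parameter:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-lim, lim, size=shape or (fan_in, fan_out)))


class Adam:
    """Adam with decoupled weight decay, matching the common
    deep-learning recipe (bias-corrected moments)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
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
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
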