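"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the conditional-flow model: broadcast-aware
arithmetic, matmul, pointwise nonlinearities, reductions, concatenation and
slicing, plus the layers (masked/plain linear, PReLU, batch norm, dropout)
and an AdamW optimizer. Every layer also exposes a graph-free ``forward_np``
path used for fast density evaluation and sampling once trained.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers --------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = prev
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def pow(self, p: float):
        def backward(g):
            return (g * p * self.data ** (p - 1.0),)
        return self._make(self.data ** p, (self,), backward)

    def matmul(self, other):
        other = self._lift(other)

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)
        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data ** 2),)
        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)
        return self._make(np.where(mask, self.data, 0.0), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)
        return self._make(out_data, (self,), backward)

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        def backward(g):
            gg = np.zeros_like(self.data)
            np.add.at(gg, idx, g)
            return (gg,)
        return self._make(self.data[idx], (self,), backward)

    @staticmethod
    def concat(tensors, axis=-1):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
        out.requires_grad = any(t.requires_grad for t in tensors)
        if out.requires_grad:
            out._prev = tuple(tensors)
            out._backward = backward
        return out

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._prev, grads):
                if p.requires_grad:
                    p.grad = g if p.grad is None else p.grad + g


# ---------------------------------------------------------------------------
# layers


class Module:
    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for e in v:
                    if isinstance(e, Module):
                        out.extend(e.parameters())
        return out

    def state_arrays(self, prefix=""):
        """Flat {name: ndarray} of parameters and buffers, for checkpoints."""
        out = {}
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[name] = v.data
            elif isinstance(v, np.ndarray):
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(name + "."))
            elif isinstance(v, (list, tuple)) and v and isinstance(v[0], Module):
                for i, e in enumerate(v):
                    out.update(e.state_arrays(f"{name}.{i}."))
        return out

    def load_state_arrays(self, arrays, prefix=""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                v.data = np.asarray(arrays[name], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(arrays[name])
            elif isinstance(v, Module):
                v.load_state_arrays(arrays, name + ".")
            elif isinstance(v, (list, tuple)) and v and isinstance(v[0], Module):
                for i, e in enumerate(v):
                    e.load_state_arrays(arrays, f"{name}.{i}.")


class Linear(Module):
    """Dense layer, optionally with a fixed binary mask on the weights."""

    def __init__(self, n_in, n_out, rng, mask=None):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-bound, bound, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.mask = None if mask is None else np.asarray(mask, float)

    def __call__(self, x: Tensor) -> Tensor:
        W = self.W if self.mask is None else self.W * Tensor(self.mask)
        return x @ W + self.b

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        W = self.W.data if self.mask is None else self.W.data * self.mask
        return x @ W + self.b.data


class PReLU(Module):
    def __init__(self, init=0.25):
        self.a = Tensor(np.array(init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.relu() - self.a * (-x).relu()

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, x, float(self.a.data) * x)


class BatchNorm(Module):
    def __init__(self, n, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xn = xc * (var + self.eps).pow(-0.5)
        else:
            xn = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return xn * self.gamma + self.beta

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xn * self.gamma.data + self.beta.data


class Dropout(Module):
    def __init__(self, rate):
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng) -> Tensor:
        if not training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


def softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy; labels are integer class indices."""
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # detached shift
    z = logits - shift
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - lse
    n = labels.shape[0]
    picked = logp[np.arange(n), labels]
    return -picked.mean()


class AdamW(Module):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
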