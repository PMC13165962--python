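"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the classifier needs (elementwise arithmetic,
matmul, 1-D convolution, reductions, activations, concatenation/slicing) with
float32 storage. Gradients of *intermediate* tensors remain available after
``backward()``, which is what Grad-CAM relies on.
"""
from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference without gradient bookkeeping)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, children, backward):
        out = Tensor(data)
        if _GRAD_ENABLED:
            out.requires_grad = any(
                isinstance(c, Tensor) and c.requires_grad for c in children
            )
            # keep graph regardless of requires_grad so intermediate grads
            # (Grad-CAM hooks) work even when no parameter is upstream
            out._prev = tuple(c for c in children if isinstance(c, Tensor))
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node.grad is not None and node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _accum(t, g):
        if isinstance(t, Tensor):
            g = _unbroadcast(np.asarray(g, dtype=np.float32), t.data.shape)
            t.grad = g if t.grad is None else t.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            Tensor._accum(self, g)
            Tensor._accum(o, g)

        return self._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            Tensor._accum(self, -g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            Tensor._accum(self, g)
            Tensor._accum(o, -g)

        return self._make(self.data - o.data, (self, o), bw)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            Tensor._accum(self, g * o.data)
            Tensor._accum(o, g * self.data)

        return self._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            Tensor._accum(self, g / o.data)
            Tensor._accum(o, -g * self.data / (o.data * o.data))

        return self._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            Tensor._accum(self, g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            Tensor._accum(self, g @ o.data.T)
            Tensor._accum(o, self.data.T @ g)

        return self._make(self.data @ o.data, (self, o), bw)

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            Tensor._accum(self, g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            Tensor._accum(self, g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            Tensor._accum(self, g * (1.0 - t * t))

        return self._make(t, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            Tensor._accum(self, g * e)

        return self._make(e, (self,), bw)

    def log(self):
        def bw(g):
            Tensor._accum(self, g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bw(g):
            Tensor._accum(self, g * 0.5 / np.maximum(r, 1e-12))

        return self._make(r, (self,), bw)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                Tensor._accum(self, np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._accum(self, np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g):
            Tensor._accum(self, g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            Tensor._accum(self, g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis (differentiable)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            Tensor._accum(self, full)

        return self._make(self.data[idx], (self,), bw)

    def detach(self):
        return Tensor(self.data.copy())


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate(datas, axis=axis)
    ref = tensors[0]

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            Tensor._accum(t, g[tuple(idx)])

    return ref._make(out_data, tuple(tensors), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same'-padded 1-D convolution.

    x: (B, C_in, T); w: (C_out, C_in, K) with odd K; b: (C_out,).
    """
    B, Cin, T = x.data.shape
    Cout, Cin2, K = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin2}")
    if K % 2 == 0:
        raise ValueError("kernel size must be odd for same padding")
    pad = dilation * (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    out = np.zeros((B, Cout, T), dtype=np.float32)
    for k in range(K):
        seg = xp[:, :, k * dilation : k * dilation + T]
        out += np.einsum("bct,oc->bot", seg, w.data[:, :, k], optimize=True)
    if b is not None:
        out += b.data[None, :, None]

    def bw(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for k in range(K):
            sl = slice(k * dilation, k * dilation + T)
            gw[:, :, k] = np.einsum("bot,bct->oc", g, xp[:, :, sl], optimize=True)
            gxp[:, :, sl] += np.einsum("bot,oc->bct", g, w.data[:, :, k], optimize=True)
        Tensor._accum(x, gxp[:, :, pad : pad + T] if pad else gxp)
        Tensor._accum(w, gw)
        if b is not None:
            Tensor._accum(b, g.sum(axis=(0, 2)))

    children = (x, w) if b is None else (x, w, b)
    return x._make(out, children, bw)


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray, class_weights=None) -> Tensor:
    """Weighted softmax cross-entropy, mean over the batch.

    labels: int array (B,); class_weights: per-class array (n_classes,) or None.
    Weighted mean uses weight normalization by the sum of sample weights, so a
    balanced batch under mean-1 weights equals the unweighted loss.
    """
    B = logits.data.shape[0]
    zmax = Tensor(logits.data.max(axis=1, keepdims=True))
    shifted = logits - zmax
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - lse  # (B, n_classes)
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(B), labels] = 1.0
    picked = (logp * Tensor(onehot)).sum(axis=1)  # (B,)
    if class_weights is None:
        return -picked.mean()
    wvec = np.asarray(class_weights, dtype=np.float32)[labels]
    return -(picked * Tensor(wvec)).sum() / float(wvec.sum())


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny layer container: registers Parameters and sub-Modules by attribute."""

    training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            items: Iterable = ()
            if isinstance(v, (Parameter, Module)):
                items = (v,)
            elif isinstance(v, (list, tuple)):
                items = v
            for item in items:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else (v,)
            for item in items:
                if isinstance(item, Module):
                    mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def _buffer_holders(self) -> list["Module"]:
        # modules with non-parameter state (e.g. batch-norm running stats)
        return [m for m in self.modules() if hasattr(m, "running_mean")]

    def state_dict(self) -> list[np.ndarray]:
        """Parameters plus running-statistic buffers, in traversal order."""
        state = [p.data.copy() for p in self.parameters()]
        for m in self._buffer_holders():
            state.append(m.running_mean.copy())
            state.append(m.running_var.copy())
            state.append(np.array([float(m._stats_initialized)]))
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        holders = self._buffer_holders()
        if len(state) != len(params) + 3 * len(holders):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = arr.copy()
        rest = state[len(params):]
        for i, m in enumerate(holders):
            m.running_mean = rest[3 * i].copy()
            m.running_var = rest[3 * i + 1].copy()
            m._stats_initialized = bool(rest[3 * i + 2][0])


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
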