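"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for the dual-branch network: a small tape-based
autodiff engine (``Tensor``), the convolution/pooling primitives the Inception
blocks need, parameterised layers, and an Adam optimizer with a cosine
learning-rate schedule.  Only the operations the model actually uses are
implemented; everything is stride-1 convolution plus strided max-pooling.

Gradient correctness is established by finite-difference checks in the test
suite rather than by construction, so each primitive keeps its backward rule
next to its forward rule.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (evaluation-mode forward passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, free_graph: bool = True) -> None:
        """Backpropagate from a scalar.

        ``free_graph`` drops the tape (closures and parent links) afterwards;
        the closures capture large intermediates and participate in reference
        cycles, so releasing them eagerly keeps training memory flat.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        if free_graph:
            for node in topo:
                # drop gradients of interior nodes; leaves and Parameters keep
                # theirs for the caller/optimizer
                if node._backward is not None and not isinstance(node, Parameter):
                    node.grad = None
                node._backward = None
                node._prev = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- construction helper ------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward(out)
        return out

    # -- elementwise arithmetic ---------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))
            return run

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            return run

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        data = np.power(self.data, exponent)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * exponent * np.power(self.data, exponent - 1.0))
            return run

        return Tensor._make(data, (self,), bw)

    __pow__ = pow

    # -- nonlinearity --------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * mask)
            return run

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * s * (1.0 - s))
            return run

        return Tensor._make(s, (self,), bw)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad * e)
            return run

        return Tensor._make(e, (self,), bw)

    def log(self) -> "Tensor":
        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad / self.data)
            return run

        return Tensor._make(np.log(self.data), (self,), bw)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(out):
            def run():
                if not self.requires_grad:
                    return
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            return run

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(out):
            def run():
                if not self.requires_grad:
                    return
                g = out.grad
                m = data
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                    m = np.expand_dims(m, axis)
                mask = self.data == m
                count = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
                self._accumulate(mask * (g / count))
            return run

        return Tensor._make(data, (self,), bw)

    def min(self, axis=None, keepdims: bool = False) -> "Tensor":
        return -((-self).max(axis=axis, keepdims=keepdims))

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad.reshape(old))
            return run

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        def bw(out):
            def run():
                if self.requires_grad:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ out.grad)
            return run

        return Tensor._make(self.data @ other.data, (self, other), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * out.grad.ndim
                    idx[axis] = slice(a, b)
                    t._accumulate(out.grad[tuple(idx)])
        return run

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# ---------------------------------------------------------------------------
# convolution / pooling primitives (NHWC, stride-1 conv)
#
# Channels-last keeps every reshape around the im2col matmul zero-copy, which
# dominates the training cost; the model converts from the public
# channels-first contract once per batch.
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, pad: int, value: float = 0.0) -> np.ndarray:
    if not pad:
        return x
    n, h, w, c = x.shape
    if value == 0.0:
        out = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=x.dtype)
    else:
        out = np.full((n, h + 2 * pad, w + 2 * pad, c), value, dtype=x.dtype)
    out[:, pad:-pad, pad:-pad, :] = x
    return out


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1×1 convolution: a single GEMM over the flattened spatial grid."""
    cin, _, _, f = weight.shape
    n, h, w, _ = x.shape
    wmat = weight.data.reshape(cin, f)
    out_data = (x.data.reshape(-1, cin) @ wmat + bias.data).reshape(n, h, w, f)

    def bw(out):
        def run():
            gmat = out.grad.reshape(-1, f)
            if weight.requires_grad:
                weight._accumulate((x.data.reshape(-1, cin).T @ gmat).reshape(weight.shape))
            if bias.requires_grad:
                bias._accumulate(gmat.sum(axis=0))
            if x.requires_grad:
                x._accumulate((gmat @ wmat.T).reshape(x.shape))
        return run

    return Tensor._make(out_data, (x, weight, bias), bw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NHWC layout.

    ``weight`` has shape (C_in, kh, kw, C_out); ``x`` is (N, H, W, C_in).
    Implemented as k² batched matmuls on shifted views, which avoids the
    strided im2col copy that otherwise dominates training time.
    """
    cin, kh, kw, f = weight.shape
    if kh == 1 and kw == 1 and padding == 0:
        return _conv1x1(x, weight, bias)
    n, h, w, _ = x.shape
    xp = _pad_hw(x.data, padding)
    ho, wo = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
    wk = np.ascontiguousarray(weight.data.transpose(1, 2, 0, 3))   # (kh, kw, C, F)
    out_data = np.empty((n, ho, wo, f), dtype=xp.dtype)
    out_data[:] = bias.data
    tmp = np.empty_like(out_data)
    for i in range(kh):
        for j in range(kw):
            np.matmul(xp[:, i:i + ho, j:j + wo, :], wk[i, j], out=tmp)
            out_data += tmp

    def bw(out):
        def run():
            gmat = out.grad.reshape(-1, f)
            if weight.requires_grad:
                dw = np.empty_like(weight.data)
                for i in range(kh):
                    for j in range(kw):
                        sl = np.ascontiguousarray(xp[:, i:i + ho, j:j + wo, :]).reshape(-1, cin)
                        dw[:, i, j, :] = sl.T @ gmat
                weight._accumulate(dw)
            if bias.requires_grad:
                bias._accumulate(gmat.sum(axis=0))
            if x.requires_grad:
                # dx is the correlation of the gradient with the flipped kernel
                gp = _pad_hw(out.grad, kh - 1 - padding)
                wb = np.ascontiguousarray(weight.data.transpose(1, 2, 3, 0)[::-1, ::-1])
                dx = np.zeros_like(x.data)
                buf = np.empty_like(dx)
                for i in range(kh):
                    for j in range(kw):
                        np.matmul(gp[:, i:i + h, j:j + w, :], wb[i, j], out=buf)
                        dx += buf
                x._accumulate(dx)
        return run

    return Tensor._make(out_data, (x, weight, bias), bw)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling, NHWC layout.  Tied maxima share the gradient equally.

    Both passes loop over the k^2 window offsets with strided slices, which
    keeps every array operation on contiguous runs.
    """
    n, h, w, c = x.shape
    xp = _pad_hw(x.data, padding, value=-np.inf)
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1

    def offset_slice(arr, i, j):
        return arr[:, i:i + (ho - 1) * stride + 1:stride,
                   j:j + (wo - 1) * stride + 1:stride, :]

    out_data = np.full((n, ho, wo, c), -np.inf, dtype=xp.dtype)
    for i in range(kernel):
        for j in range(kernel):
            np.maximum(out_data, offset_slice(xp, i, j), out=out_data)

    def bw(out):
        def run():
            if not x.requires_grad:
                return
            count = np.zeros(out_data.shape, dtype=xp.dtype)
            for i in range(kernel):
                for j in range(kernel):
                    count += offset_slice(xp, i, j) == out_data
            share = out.grad / count
            dxp = np.zeros_like(xp)
            for i in range(kernel):
                for j in range(kernel):
                    sl = offset_slice(xp, i, j)
                    offset_slice(dxp, i, j)[...] += (sl == out_data) * share
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding, :]
            x._accumulate(dxp)
        return run

    return Tensor._make(out_data, (x,), bw)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def train(self) -> "Module":
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self) -> "Module":
        self.train()
        # flip flags set by train(); cheaper than duplicating the walk
        def _set(m: Module):
            m.training = False
            for v in m.__dict__.values():
                if isinstance(v, Module):
                    _set(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            _set(item)
        _set(self)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(m: Module, prefix: str):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    out[prefix + k] = v.data.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")
        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def walk(m: Module, prefix: str):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[prefix + k]).copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")
        walk(self, "")


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                    dtype=np.float64) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    """NHWC convolution layer; weights stored (C_in, kh, kw, C_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_fan_in_uniform(rng, (in_channels, kernel, kernel, out_channels), fan_in, dtype))
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in, dtype))
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_fan_in_uniform(rng, (in_features, out_features), in_features, dtype))
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-p) so eval needs no rescale."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask.astype(x.data.dtype))


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the (beta1, beta2) = (0.5, 0.999) setting used for training."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
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
        alpha = self.lr / (1 - self.b1 ** self.t)
        root_bc2 = math.sqrt(1 - self.b2 ** self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            denom = np.sqrt(v)
            denom /= root_bc2
            denom += self.eps
            np.divide(m, denom, out=denom)
            denom *= alpha
            p.data -= denom


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``base_lr`` to 0 over ``total_epochs``."""
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / max(total_epochs, 1)))
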