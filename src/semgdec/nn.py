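"""Minimal reverse-mode automatic differentiation over NumPy arrays, plus
the handful of neural-network layers the decoder needs.

This is a deliberately small engine: a :class:`Tensor` wraps an ndarray
and records a closure that routes the upstream gradient to its parents;
``backward()`` walks the graph in reverse topological order.  Only the
operations the transformer uses are implemented (broadcast arithmetic,
matmul, reshape/transpose, reductions, softmax, layer norm, GELU,
dropout).  Gradients are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: Array | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.value = np.asarray(value)
        if self.value.dtype not in (np.float32, np.float64):
            self.value = self.value.astype(np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph mechanics -------------------------------------------------

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=self.value.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other): return add(self, other)
    __radd__ = __add__

    def __neg__(self): return mul(self, -1.0)

    def __sub__(self, other): return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other): return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other): return mul(self, other)
    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(other, -1.0))

    def __matmul__(self, other): return matmul(self, other)

    def __pow__(self, p: float): return pow_(self, p)

    def reshape(self, *shape): return reshape(self, shape)

    def transpose(self, *axes): return transpose(self, axes)

    def sum(self, axis=None, keepdims=False): return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False): return mean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _aligned(a: Tensor, b: Tensor) -> tuple[Array, Array]:
    """Operand values with 0-d constants cast to the array operand's dtype,
    so float32 graphs are not silently upcast by scalar constants."""
    av, bv = a.value, b.value
    if av.dtype != bv.dtype:
        if bv.ndim == 0:
            bv = bv.astype(av.dtype)
        elif av.ndim == 0:
            av = av.astype(bv.dtype)
    return av, bv


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    av, bv = _aligned(a, b)
    out_val = av + bv

    def bwd(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=bwd)


def mul(a: Tensor, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    av, bv = _aligned(a, b)
    out_val = av * bv

    def bwd(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * bv, a.value.shape).astype(a.value.dtype))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * av, b.value.shape).astype(b.value.dtype))

    return Tensor(out_val, parents=(a, b), backward=bwd)


def pow_(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    out_val = a.value**p

    def bwd(g: Array) -> None:
        a._accumulate(g * p * a.value ** (p - 1))

    return Tensor(out_val, parents=(a,), backward=bwd)


def abs_(a: Tensor) -> Tensor:
    a = _as_tensor(a)

    def bwd(g: Array) -> None:
        a._accumulate(g * np.sign(a.value))

    return Tensor(np.abs(a.value), parents=(a,), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value @ b.value

    def bwd(g: Array) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.value, -1, -2)
            a._accumulate(_unbroadcast(ga, a.value.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.value, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=bwd)


def reshape(a: Tensor, shape: Sequence[int]) -> Tensor:
    a = _as_tensor(a)
    orig = a.value.shape

    def bwd(g: Array) -> None:
        a._accumulate(g.reshape(orig))

    return Tensor(a.value.reshape(shape), parents=(a,), backward=bwd)


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def bwd(g: Array) -> None:
        a._accumulate(g.transpose(inv))

    return Tensor(a.value.transpose(axes), parents=(a,), backward=bwd)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def bwd(g: Array) -> None:
        gg = g
        if not keepdims and axis is not None:
            gg = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(gg, a.value.shape).copy())

    return Tensor(out_val, parents=(a,), backward=bwd)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.value.size if axis is None else np.prod(
        [a.value.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g: Array) -> None:
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return Tensor(y, parents=(a,), backward=bwd)


def gelu(a: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    a = _as_tensor(a)
    c = math.sqrt(2.0 / math.pi)
    x = a.value
    x2 = x * x  # x*x avoids numpy's slow float32 pow path
    inner = c * (x + 0.044715 * x2 * x)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def bwd(g: Array) -> None:
        sech2 = 1.0 - t * t
        dinner = c * (1.0 + 3 * 0.044715 * x2)
        dy = 0.5 * (1.0 + t) + 0.5 * x * sech2 * dinner
        a._accumulate(g * dy)

    return Tensor(y, parents=(a,), backward=bwd)


def layer_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis to zero mean, unit variance."""
    a = _as_tensor(a)
    x = a.value
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    n = x.shape[-1]

    def bwd(g: Array) -> None:
        gy = g * inv
        a._accumulate(
            gy
            - gy.mean(axis=-1, keepdims=True)
            - y * (gy * y).mean(axis=-1, keepdims=True)
        )

    return Tensor(y, parents=(a,), backward=bwd)


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return a
    a = _as_tensor(a)
    mask = (rng.random(a.value.shape) >= p) / (1.0 - p)

    def bwd(g: Array) -> None:
        a._accumulate(g * mask)

    return Tensor(a.value * mask, parents=(a,), backward=bwd)


def mse_loss(pred: Tensor, target: Array) -> Tensor:
    diff = pred - Tensor(target)
    return mean(pow_(diff, 2.0))


def mae_loss(pred: Tensor, target: Array) -> Tensor:
    return mean(abs_(pred - Tensor(target)))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, value: Array, name: str = ""):
        super().__init__(value, requires_grad=True)
        self.name = name

    __slots__ = ("name",)


class Module:
    """Container base: recursively exposes parameters()."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
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

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def state(self) -> list[Array]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[Array]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {v.shape}")
            p.value = v.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = "linear"):
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.w = Parameter(rng.uniform(-bound, bound, (d_in, d_out)), f"{name}.w")
        self.b = Parameter(np.zeros(d_out), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, name: str = "ln"):
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over axis -2 of (B, T, D)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, name: str = "mhsa"):
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.qkv = Linear(dim, 3 * dim, rng, f"{name}.qkv")
        self.proj = Linear(dim, dim, rng, f"{name}.proj")

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h = self.n_heads
        dh = d // h
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = reshape(qkv, (b, t, 3, h, dh))
        qkv = transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, H, T, dh)
        # Slices of the leading axis via reshape-free indexing:
        q = _take_first_axis(qkv, 0)
        k = _take_first_axis(qkv, 1)
        v = _take_first_axis(qkv, 2)
        scores = matmul(q, transpose(k, (0, 1, 3, 2))) * (1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        out = matmul(attn, v)  # (B, H, T, dh)
        out = transpose(out, (0, 2, 1, 3))
        out = reshape(out, (b, t, d))
        return self.proj(out)


def _take_first_axis(a: Tensor, index: int) -> Tensor:
    """Select ``a[index]`` along axis 0, differentiable."""

    def bwd(g: Array) -> None:
        full = np.zeros_like(a.value)
        full[index] = g
        a._accumulate(full)

    return Tensor(a.value[index], parents=(a,), backward=bwd)


class EncoderLayer(Module):
    """Pre-norm transformer encoder block: x + MHSA(LN(x)); x + MLP(LN(x))."""

    def __init__(
        self,
        dim: int,
        n_heads: int,
        mlp_ratio: float,
        dropout_p: float,
        rng: np.random.Generator,
        name: str = "enc",
    ):
        hidden = int(round(dim * mlp_ratio))
        self.ln1 = LayerNorm(dim, f"{name}.ln1")
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, f"{name}.attn")
        self.ln2 = LayerNorm(dim, f"{name}.ln2")
        self.fc1 = Linear(dim, hidden, rng, f"{name}.fc1")
        self.fc2 = Linear(hidden, dim, rng, f"{name}.fc2")
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        x = x + dropout(self.attn(self.ln1(x)), self.dropout_p, rng, training)
        x = x + dropout(
            self.fc2(gelu(self.fc1(self.ln2(x)))), self.dropout_p, rng, training
        )
        return x


class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
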