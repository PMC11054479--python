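"""Minimal reverse-mode automatic differentiation on NumPy.

A small, self-contained tensor engine providing exactly the operations the
segmentation network needs: broadcast arithmetic, batched matmul, grouped 2-D
convolution, layer normalization, softmax / log-softmax, GELU (exact erf
form), sigmoid, ReLU, bilinear resampling, reductions, reshaping, slicing,
padding and cyclic roll — each with an analytic backward pass — plus a
``Module`` parameter container and an AdamW optimizer.

Gradients are accumulated into ``Tensor.grad`` by ``Tensor.backward()`` via a
topological sweep of the recorded graph.  All arithmetic is float64.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "bilinear_resize",
    "Module",
    "ModuleList",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "layer_norm",
    "AdamW",
    "trunc_normal",
    "numerical_grad",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # method-style ops
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return reduce_max(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], list] | None) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        for p in parents:
            if p.requires_grad or p._backward is not None:
                out._parents = tuple(parents)
                out._backward = backward
                break
    return out


# ---------------------------------------------------------------------------
# elementwise & arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return [(a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))]

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return [(a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape))]

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def backward(g):
        return [(a, g * p * a.data ** (p - 1.0))]

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return [(a, g * data)]

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return [(a, g / a.data)]

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = expit(a.data)  # overflow-safe logistic

    def backward(g):
        return [(a, g * data * (1.0 - data))]

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        return [(a, g * mask)]

    return _make(data, (a,), backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    """Exact (erf-form) Gaussian error linear unit."""
    a = _as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data / _SQRT2))
    data = a.data * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data ** 2)
        return [(a, g * (cdf + a.data * pdf))]

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return [(a, data * (g - dot))]

    return _make(data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse
    sm = np.exp(data)

    def backward(g):
        return [(a, g - sm * g.sum(axis=axis, keepdims=True))]

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    data = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return [(a, np.broadcast_to(g, a.shape).copy())]

    return _make(data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    count = math.prod(a.shape[ax] for ax in axes)
    data = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return [(a, np.broadcast_to(g, a.shape) / count)]

    return _make(data, (a,), backward)


def reduce_max(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    kept = a.data.max(axis=axes, keepdims=True)
    data = kept if keepdims else kept.squeeze(axes)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        mask = (a.data == kept)
        # split gradient evenly across ties
        counts = mask.sum(axis=axes, keepdims=True)
        return [(a, np.broadcast_to(g, a.shape) * mask / counts)]

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return [(a, g.reshape(a.shape))]

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return [(a, g.transpose(inv))]

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]

    def backward(g):
        out = np.zeros(a.shape)
        np.add.at(out, idx, g)
        return [(a, out)]

    return _make(data, (a,), backward)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return _make(data, tuple(tensors), backward)


def pad2d(a, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the last two axes by (top, bottom, left, right)."""
    a = _as_tensor(a)
    t, b, l, r = pad
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    data = np.pad(a.data, width)
    sl = (Ellipsis, slice(t, data.shape[-2] - b), slice(l, data.shape[-1] - r))

    def backward(g):
        return [(a, g[sl])]

    return _make(data, (a,), backward)


def roll(a, shifts, axes) -> Tensor:
    a = _as_tensor(a)
    data = np.roll(a.data, shifts, axis=axes)
    neg = tuple(-s for s in shifts) if isinstance(shifts, tuple) else -shifts

    def backward(g):
        return [(a, np.roll(g, neg, axis=axes))]

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix multiply with NumPy broadcast semantics."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return [(a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape))]

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# 2-D convolution (grouped, strided, zero-padded) via im2col
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Cross-correlation of NCHW input ``x`` with OIHW weight ``w``.

    ``groups=C_in`` with one-channel weight slices gives depthwise convolution.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    if Cin % groups or Cout % groups or Cin // groups != Cin_g:
        raise ValueError(
            f"conv2d channel/group mismatch: in={Cin}, weight expects "
            f"{Cin_g}x{groups} grouped input channels, out={Cout}")
    s, p = stride, padding
    depthwise = groups == Cin == Cout and Cin_g == 1

    # fast path: 1x1 kernel, stride 1, no padding — a channel matmul
    if kh == kw == 1 and s == 1 and p == 0 and groups == 1:
        w2 = w.data[:, :, 0, 0]
        out = np.einsum("oi,bihw->bohw", w2, x.data, optimize=True)
        if b is not None:
            out = out + b.data.reshape(1, Cout, 1, 1)

        def backward_1x1(g):
            gx = np.einsum("oi,bohw->bihw", w2, g, optimize=True)
            gw = np.einsum("bihw,bohw->oi", x.data, g,
                           optimize=True)[:, :, None, None].copy()
            grads = [(x, gx), (w, gw.reshape(w.shape))]
            if b is not None:
                grads.append((b, g.sum(axis=(0, 2, 3))))
            return grads

        parents = (x, w) if b is None else (x, w, b)
        return _make(out, parents, backward_1x1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[-2:]
    Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
    # (B, Cin, Ho, Wo, kh, kw) strided view — no copy
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = cols[:, :, ::s, ::s, :, :]

    if depthwise:
        out = np.einsum("bchwkl,ckl->bchw", cols, w.data[:, 0], optimize=True)
    elif groups == 1:
        out = np.einsum("bihwkl,oikl->bohw", cols, w.data, optimize=True)
    else:
        cols_g = cols.reshape(B, groups, Cin_g, Ho, Wo, kh, kw)
        w_g = w.data.reshape(groups, Cout // groups, Cin_g, kh, kw)
        out = np.einsum("bgihwkl,goikl->bgohw", cols_g, w_g,
                        optimize=True).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def backward(g):
        dxp = np.zeros((B, Cin, Hp, Wp))
        if depthwise:
            gw = np.einsum("bchwkl,bchw->ckl", cols, g,
                           optimize=True)[:, None]
            wd = w.data[:, 0]
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        g * wd[None, :, i, j, None, None]
        elif groups == 1:
            gw = np.einsum("bihwkl,bohw->oikl", cols, g, optimize=True)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        np.einsum("oi,bohw->bihw", w.data[:, :, i, j], g,
                                  optimize=True)
        else:
            gg = g.reshape(B, groups, Cout // groups, Ho, Wo)
            gw = np.einsum("bgihwkl,bgohw->goikl", cols_g, gg,
                           optimize=True).reshape(w.shape)
            dcols = np.einsum("goikl,bgohw->bgihwkl", w_g, gg,
                              optimize=True).reshape(B, Cin, Ho, Wo, kh, kw)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        dcols[:, :, :, :, i, j]
        dx = dxp[:, :, p:Hp - p, p:Wp - p] if p else dxp
        grads = [(x, dx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# bilinear resampling (separable, align_corners=False convention)
# ---------------------------------------------------------------------------

def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) bilinear interpolation matrix, align_corners=False."""
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    lo = np.clip(np.floor(coords).astype(int), 0, n_in - 1)
    # edge clamp: fraction measured after clipping so borders replicate
    frac = np.clip(coords, 0, n_in - 1) - lo
    hi = np.clip(lo + 1, 0, n_in - 1)
    m = np.zeros((n_out, n_in))
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the last two axes of an NCHW tensor (separable)."""
    x = _as_tensor(x)
    _, _, H, W = x.shape
    Rh = _interp_matrix(H, out_h)
    Rw = _interp_matrix(W, out_w)
    tmp = np.einsum("oh,bchw->bcow", Rh, x.data, optimize=True)
    data = np.einsum("pw,bcow->bcop", Rw, tmp, optimize=True)

    def backward(g):
        gtmp = np.einsum("pw,bcop->bcow", Rw, g, optimize=True)
        gx = np.einsum("oh,bcow->bchw", Rh, gtmp, optimize=True)
        return [(x, gx)]

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# modules & layers
# ---------------------------------------------------------------------------

def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped to ±2 std (truncated-normal initializer)."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


class Module:
    """Parameter container with recursive traversal, torch-style."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)[:5]}, "
                           f"unexpected={sorted(extra)[:5]}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods: Sequence[Module] = ()):  # noqa: D107
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m: Module) -> None:
        self.items.append(m)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(trunc_normal(rng, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 groups: int = 1, bias: bool = True):
        self.stride, self.padding, self.groups = stride, padding, groups
        self.weight = Tensor(
            trunc_normal(rng, (out_ch, in_ch // groups, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


def layer_norm(x, w, b, axis: int, eps: float = 1e-6) -> Tensor:
    """Fused layer normalization over ``axis`` with affine weight/bias."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    ax = axis % x.ndim
    mu = x.data.mean(axis=ax, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    bshape = [1] * x.ndim
    bshape[ax] = x.shape[ax]
    wr = w.data.reshape(bshape)
    data = xhat * wr + b.data.reshape(bshape)
    reduce_axes = tuple(i for i in range(x.ndim) if i != ax)

    def backward(g):
        gw = (g * xhat).sum(axis=reduce_axes)
        gb = g.sum(axis=reduce_axes)
        gxhat = g * wr
        m1 = gxhat.mean(axis=ax, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=ax, keepdims=True)
        return [(x, inv * (gxhat - m1 - xhat * m2)), (w, gw), (b, gb)]

    return _make(data, (x, w, b), backward)


class LayerNorm(Module):
    """Layer normalization over the channel axis of an NCHW feature map.

    Statistics are computed per (batch, y, x) position across channels
    (channels-last convention transposed into NCHW layout); token layouts
    (..., C) normalize over the last axis.
    """

    def __init__(self, channels: int, eps: float = 1e-6):
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axis = 1 if x.ndim == 4 else -1
        return layer_norm(x, self.weight, self.bias, axis, self.eps)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# finite-difference gradient check (test utility)
# ---------------------------------------------------------------------------

def numerical_grad(fn: Callable[[np.ndarray], float], x: np.ndarray,
                   eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``fn`` at ``x``."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
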