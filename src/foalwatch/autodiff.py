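"""Minimal reverse-mode automatic differentiation on numpy arrays.

The detector in this package is small enough that a tape-based engine over
float64 numpy arrays is fast and exactly reproducible on a CPU.  Only the
operations the model needs are implemented: broadcasting arithmetic,
matmul, convolution via im2col, pooling, resizing, gather-style bilinear
sampling, and the usual pointwise nonlinearities.

Conventions: feature maps are NCHW; gradients accumulate into ``Tensor.grad``
after ``Tensor.backward()``; ``no_grad()`` disables tape recording.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that suspends graph recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative DFS topological sort (deep graphs exceed recursion limits)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(p)
                grads[key] = grads[key] + pg if key in grads else pg

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(
        p.requires_grad or p._backward is not None or p._parents for p in parents
    ):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _make(data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def backward(g):
        return (g * p * a.data ** (p - 1.0),)

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _make(data, (a, b), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return (g * data,)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        return (g * mask,)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return (g * data * (1.0 - data),)

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return (data * (g - dot),)

    return _make(data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse
    soft = np.exp(data)

    def backward(g):
        return (g - soft * g.sum(axis=axis, keepdims=True),)

    return _make(data, (a,), backward)


# -- shape ops ----------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.shape),)

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        return (g.transpose(inv),)

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return (out,)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return _make(data, tuple(tensors), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def max_(a, axis, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data)
    # split ties evenly so the gradient stays well-defined
    mask = mask / mask.sum(axis=axis, keepdims=True)
    out = data if keepdims else np.squeeze(data, axis=axis)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (g * mask,)

    return _make(out, (a,), backward)


def pad2d(a, pad: int, mode: str = "zero") -> Tensor:
    """Pad the last two axes by ``pad`` on every side."""
    a = as_tensor(a)
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    if mode == "zero":
        data = np.pad(a.data, width)
    elif mode == "edge":
        data = np.pad(a.data, width, mode="edge")
    else:
        raise ValueError(f"unknown pad mode {mode!r}")

    def backward(g):
        core = g[..., pad:-pad, pad:-pad]
        if mode == "zero":
            return (core.copy(),)
        # edge padding folds border gradients back onto the edge pixels
        out = np.zeros_like(a.data)
        H, W = a.shape[-2], a.shape[-1]
        ii = np.clip(np.arange(-pad, H + pad), 0, H - 1)
        jj = np.clip(np.arange(-pad, W + pad), 0, W - 1)
        np.add.at(out, (..., ii[:, None], jj[None, :]), g)
        return (out,)

    return _make(data, (a,), backward)


# -- conv / pooling -----------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, out_h*out_w) using stride tricks."""
    N, C, H, W = x.shape
    out_h = (H - k) // stride + 1
    out_w = (W - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(N, C, out_h, out_w, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    return (
        windows.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * k * k, out_h * out_w),
        out_h,
        out_w,
    )


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    N, C, H, W = x_shape
    out_h = (H - k) // stride + 1
    out_w = (W - k) // stride + 1
    cols = cols.reshape(N, C, k, k, out_h, out_w)
    x = np.zeros((N, C, H, W))
    for i in range(k):
        for j in range(k):
            x[:, :, i : i + stride * out_h : stride, j : j + stride * out_w : stride] += cols[
                :, :, i, j
            ]
    return x


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution; ``weight`` is (O, I, k, k)."""
    x, weight = as_tensor(x), as_tensor(weight)
    k = weight.shape[-1]
    xp = pad2d(x, padding) if padding else x
    xd = xp.data
    N, C, H, W = xd.shape
    O = weight.shape[0]
    cols, out_h, out_w = _im2col(xd, k, stride)
    cols = np.ascontiguousarray(cols)
    wmat = weight.data.reshape(O, -1)
    out = (wmat[None] @ cols).reshape(N, O, out_h, out_w)
    if bias is not None:
        out = out + as_tensor(bias).data.reshape(1, O, 1, 1)
    parents = (xp, weight) if bias is None else (xp, weight, as_tensor(bias))

    def backward(g):
        gmat = np.ascontiguousarray(g.reshape(N, O, out_h * out_w))
        gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
        gcols = wmat.T[None] @ gmat
        gx = _col2im(gcols, xd.shape, k, stride)
        if bias is not None:
            gb = g.sum(axis=(0, 2, 3))
            return gx, gw, gb
        return gx, gw

    out_t = _make(out, parents, backward)
    return out_t


def avg_pool2d(x, k: int, stride: int | None = None) -> Tensor:
    x = as_tensor(x)
    stride = stride or k
    xd = x.data
    N, C, H, W = xd.shape
    cols, out_h, out_w = _im2col(xd, k, stride)
    cols = cols.reshape(N, C, k * k, out_h * out_w)
    out = cols.mean(axis=2).reshape(N, C, out_h, out_w)

    def backward(g):
        gcols = np.repeat(
            g.reshape(N, C, 1, out_h * out_w) / (k * k), k * k, axis=2
        ).reshape(N, C * k * k, out_h * out_w)
        return (_col2im(gcols, xd.shape, k, stride),)

    return _make(out, (x,), backward)


def max_pool2d(x, k: int, stride: int | None = None) -> Tensor:
    x = as_tensor(x)
    stride = stride or k
    xd = x.data
    N, C, H, W = xd.shape
    cols, out_h, out_w = _im2col(xd, k, stride)
    cols = cols.reshape(N, C, k * k, out_h * out_w)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :].reshape(
        N, C, out_h, out_w
    )

    def backward(g):
        gcols = np.zeros((N, C, k * k, out_h * out_w))
        np.put_along_axis(
            gcols, arg[:, :, None, :], g.reshape(N, C, 1, out_h * out_w), axis=2
        )
        return (_col2im(gcols.reshape(N, C * k * k, -1), xd.shape, k, stride),)

    return _make(out, (x,), backward)


def subsample2(x) -> Tensor:
    """Stride-2 spatial subsampling (k=1, s=2 pooling)."""
    x = as_tensor(x)
    data = x.data[..., ::2, ::2].copy()

    def backward(g):
        out = np.zeros_like(x.data)
        out[..., ::2, ::2] = g
        return (out,)

    return _make(data, (x,), backward)


def nearest_resize(x, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize of the last two axes to ``size``."""
    x = as_tensor(x)
    H, W = x.shape[-2], x.shape[-1]
    oh, ow = size
    ii = np.floor(np.arange(oh) * H / oh).astype(int)
    jj = np.floor(np.arange(ow) * W / ow).astype(int)
    data = x.data[..., ii[:, None], jj[None, :]]

    def backward(g):
        out = np.zeros_like(x.data)
        np.add.at(out, (..., ii[:, None], jj[None, :]), g)
        return (out,)

    return _make(data, (x,), backward)


def adaptive_avg_pool(x, size: tuple[int, int]) -> Tensor:
    """Average pooling to an arbitrary target size (deterministic bins)."""
    x = as_tensor(x)
    H, W = x.shape[-2], x.shape[-1]
    oh, ow = size
    hs = [(math.floor(i * H / oh), math.ceil((i + 1) * H / oh)) for i in range(oh)]
    ws = [(math.floor(j * W / ow), math.ceil((j + 1) * W / ow)) for j in range(ow)]
    out = np.empty(x.shape[:-2] + (oh, ow))
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            out[..., i, j] = x.data[..., h0:h1, w0:w1].mean(axis=(-2, -1))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                area = (h1 - h0) * (w1 - w0)
                gx[..., h0:h1, w0:w1] += g[..., i : i + 1, j : j + 1] / area
        return (gx,)

    return _make(out, (x,), backward)


def unfold_neighborhoods(x, k: int, pad_mode: str = "zero") -> Tensor:
    """(N,C,H,W) -> (N,C,k*k,H,W): the k×k neighbourhood of every pixel."""
    if k % 2 != 1:
        raise ValueError("neighbourhood size must be odd")
    x = as_tensor(x)
    p = k // 2
    xp = pad2d(x, p, mode=pad_mode)
    xd = xp.data
    N, C, Hp, Wp = xd.shape
    H, W = Hp - 2 * p, Wp - 2 * p
    s0, s1, s2, s3 = xd.strides
    windows = np.lib.stride_tricks.as_strided(
        xd,
        shape=(N, C, H, W, k, k),
        strides=(s0, s1, s2, s3, s2, s3),
        writeable=False,
    )
    data = windows.transpose(0, 1, 4, 5, 2, 3).reshape(N, C, k * k, H, W).copy()

    def backward(g):
        g = g.reshape(N, C, k, k, H, W)
        gx = np.zeros_like(xd)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + H, j : j + W] += g[:, :, i, j]
        return (gx,)

    return _make(data, (xp,), backward)


# -- modules ------------------------------------------------------------

class Module:
    """Barebones module container: named parameters, train/eval flag."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        def walk(name: str, val):
            if isinstance(val, Tensor):
                if val.requires_grad:
                    yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{name}.{i}", item)

        for name, val in vars(self).items():
            yield from walk(f"{prefix}{name}", val)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterable["Module"]:
        def walk(val):
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    yield from walk(item)

        yield self
        for val in vars(self).values():
            yield from walk(val)

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def named_modules(self, prefix: str = "") -> Iterable[tuple[str, "Module"]]:
        def walk(name: str, val):
            if isinstance(val, Module):
                yield from val.named_modules(name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{name}.{i}", item)

        yield prefix.rstrip("."), self
        for name, val in vars(self).items():
            yield from walk(f"{prefix}{name}", val)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, m in self.named_modules():
            for b in getattr(m, "_buffer_names", ()):
                state[f"{name}.{b}" if name else b] = np.copy(getattr(m, b))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data = np.asarray(state[k], dtype=np.float64).reshape(v.shape)
        for name, m in self.named_modules():
            for b in getattr(m, "_buffer_names", ()):
                key = f"{name}.{b}" if name else b
                if key in state:
                    setattr(m, b, np.asarray(state[key], dtype=np.float64))


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Tensor(
            _kaiming(rng, (c_out, c_in, k, k), c_in * k * k), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x):
        return matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, c, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        # when set, eval mode still normalises with the current batch's
        # statistics (without updating the running averages)
        self.use_batch_stats = False

    def forward(self, x):
        x = as_tensor(x)
        shape = (1, -1, 1, 1)
        if self.training or self.use_batch_stats:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            if self.training:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return _batch_norm_train(x, self.gamma, self.beta, mu, var, self.eps)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = mul(add(x, (-self.running_mean).reshape(shape)), inv.reshape(shape))
        return add(
            mul(xhat, reshape(self.gamma, shape)), reshape(self.beta, shape)
        )


def _batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                      mu: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    """Batch norm with gradients through the batch statistics."""
    shape = (1, -1, 1, 1)
    inv = (1.0 / np.sqrt(var + eps)).reshape(shape)
    xhat = (x.data - mu.reshape(shape)) * inv
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    axes = (0, 2, 3)

    def backward(g):
        dxhat = g * gamma.data.reshape(shape)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        gx = inv * (dxhat - m1 - xhat * m2)
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        return gx, dgamma, dbeta

    return _make(out, (x, gamma, beta), backward)


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
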