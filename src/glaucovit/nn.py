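"""A compact reverse-mode autodiff core and the layers built on it.

All neural components of the package (the conditional GAN and the
transformer classifier) run on this engine.  Design points:

* A :class:`Tensor` wraps a float64 numpy array and records its parents and
  a backward closure.  Backward closures are themselves written in tensor
  operations, so differentiating through a gradient — as the
  Wasserstein-GAN gradient penalty requires — works out of the box.
* Only the primitives the models need exist: elementwise arithmetic,
  matmul (with broadcasting), reductions, reshapes, padding/slicing, and a
  gather/scatter pair that turns convolution into im2col + matmul.
* Everything is deterministic given the numpy Generator used for
  initialization and data order; there is no hidden global state.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64) if x.dtype != np.float64 else x
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Array | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_ensure(other))

    def __rsub__(self, other):
        return add(_ensure(other), -self)

    def __truediv__(self, other):
        return mul(self, power(_ensure(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents), backward=backward if req else None)


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# -- primitives ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def backward(g: Tensor):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def backward(g: Tensor):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return _make(a.data * b.data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _ensure(a)
    p = float(p)

    def backward(g: Tensor):
        return (mul(g, mul(p, power(a, p - 1.0))),)

    return _make(a.data**p, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def backward(g: Tensor):
        ga = matmul(g, swap_last(b))
        gb = matmul(swap_last(a), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _make(np.matmul(a.data, b.data), (a, b), backward)


def swap_last(a: Tensor) -> Tensor:
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def exp(a) -> Tensor:
    a = _ensure(a)
    out = _make(np.exp(a.data), (a,), None)

    def backward(g: Tensor):
        # reference the output tensor itself so d(exp)/da stays in the graph
        return (mul(g, out),)

    out._backward = backward if out.requires_grad else None
    return out


def log(a) -> Tensor:
    a = _ensure(a)

    def backward(g: Tensor):
        return (mul(g, power(a, -1.0)),)

    return _make(np.log(a.data), (a,), backward)


def tanh(a) -> Tensor:
    a = _ensure(a)
    out = _make(np.tanh(a.data), (a,), None)

    def backward(g: Tensor):
        return (mul(g, 1.0 - mul(out, out)),)

    out._backward = backward if out.requires_grad else None
    return out


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tabs(a) -> Tensor:
    a = _ensure(a)
    sign = np.sign(a.data)

    def backward(g: Tensor):
        return (mul(g, Tensor(sign)),)

    return _make(np.abs(a.data), (a,), backward)


def clamp_min(a, lo: float) -> Tensor:
    a = _ensure(a)
    mask = (a.data >= lo).astype(np.float64)

    def backward(g: Tensor):
        return (mul(g, Tensor(mask)),)

    return _make(np.maximum(a.data, lo), (a,), backward)


def relu(a) -> Tensor:
    a = _ensure(a)
    mask = (a.data > 0).astype(np.float64)

    def backward(g: Tensor):
        return (mul(g, Tensor(mask)),)

    return _make(a.data * mask, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _ensure(a)
    fac = np.where(a.data > 0, 1.0, slope)

    def backward(g: Tensor):
        return (mul(g, Tensor(fac)),)

    return _make(a.data * fac, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        axis_t = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axis_t = (axis % a.ndim,)
    else:
        axis_t = tuple(ax % a.ndim for ax in axis)
    kept_shape = tuple(1 if i in axis_t else n for i, n in enumerate(a.shape))

    def backward(g: Tensor):
        return (broadcast_to(reshape(g, kept_shape), a.shape),)

    return _make(np.sum(a.data, axis=axis_t, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, int):
        n = a.shape[axis]
    else:
        n = int(np.prod([a.shape[ax] for ax in axis]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape) -> Tensor:
    a = _ensure(a)
    shape = tuple(shape)

    def backward(g: Tensor):
        return (_unbroadcast(g, a.shape),)

    return _make(np.broadcast_to(a.data, shape).copy(), (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    orig = a.shape
    shape = tuple(shape)
    if orig == shape:
        return a

    def backward(g: Tensor):
        return (reshape(g, orig),)

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _ensure(a)
    axes = tuple(axes)
    inv = tuple(int(i) for i in np.argsort(axes))

    def backward(g: Tensor):
        return (transpose(g, inv),)

    return _make(np.transpose(a.data, axes), (a,), backward)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [_ensure(t) for t in tensors]
    axis = axis % ts[0].ndim
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Tensor):
        grads = []
        for i, t in enumerate(ts):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(slice_op(g, tuple(sl)))
        return tuple(grads)

    return _make(np.concatenate([t.data for t in ts], axis=axis), ts, backward)


def slice_op(a, slices) -> Tensor:
    a = _ensure(a)
    orig_shape = a.shape

    def backward(g: Tensor):
        return (unslice(g, slices, orig_shape),)

    return _make(a.data[slices], (a,), backward)


def unslice(g, slices, shape) -> Tensor:
    g = _ensure(g)

    def backward(gg: Tensor):
        return (slice_op(gg, slices),)

    out_data = np.zeros(shape, dtype=np.float64)
    out_data[slices] = g.data
    return _make(out_data, (g,), backward)


def pad2d(a, p: int) -> Tensor:
    """Zero-pad the last two axes by ``p`` on each side."""
    if p == 0:
        return _ensure(a)
    a = _ensure(a)
    width = [(0, 0)] * (a.ndim - 2) + [(p, p), (p, p)]
    sl = (Ellipsis, slice(p, a.shape[-2] + p), slice(p, a.shape[-1] + p))

    def backward(g: Tensor):
        return (slice_op(g, sl),)

    return _make(np.pad(a.data, width), (a,), backward)


def take_patches(a, ri: Array, ci: Array) -> Tensor:
    """Advanced gather on the last two axes: ``y[..., u, v] = a[..., ri[u, v], ci[u, v]]``."""
    a = _ensure(a)
    shape = a.shape

    def backward(g: Tensor):
        return (scatter_patches(g, ri, ci, shape),)

    return _make(a.data[..., ri, ci], (a,), backward)


def scatter_patches(g, ri: Array, ci: Array, shape) -> Tensor:
    """Adjoint of :func:`take_patches`: scatter-add into a zero grid."""
    g = _ensure(g)
    lead = shape[:-2]
    hp, wp = shape[-2], shape[-1]
    nlead = int(np.prod(lead)) if lead else 1
    flat_idx = (ri * wp + ci).ravel()
    gd = g.data.reshape(nlead, flat_idx.size)
    out_data = np.zeros((nlead, hp * wp), dtype=np.float64)
    np.add.at(out_data, (np.arange(nlead)[:, None], flat_idx[None, :]), gd)
    out_data = out_data.reshape(shape)

    def backward(gg: Tensor):
        return (take_patches(gg, ri, ci),)

    return _make(out_data, (g,), backward)


def upsample2x(a) -> Tensor:
    """Nearest-neighbour 2x upsampling of the last two axes."""
    a = _ensure(a)
    lead = a.shape[:-2]
    h, w = a.shape[-2:]

    def backward(g: Tensor):
        g6 = reshape(g, lead + (h, 2, w, 2))
        return (tsum(g6, axis=(len(lead) + 1, len(lead) + 3)),)

    out_data = np.repeat(np.repeat(a.data, 2, axis=-2), 2, axis=-1)
    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _ensure(a)
    shift = a - Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(shift)
    return e / tsum(e, axis=axis, keepdims=True)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _ensure(a)
    shift = a - Tensor(np.max(a.data, axis=axis, keepdims=True))
    return shift - log(tsum(exp(shift), axis=axis, keepdims=True))


# -- engine --------------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs: Sequence[Tensor], grad_output: Tensor | None = None) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    The returned tensors carry their own computation graph, so a second
    :func:`grad` through them yields higher-order derivatives.
    """
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("output must be scalar unless grad_output is given")
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(_topo_order(output)):
        g = grads.get(id(node))
        if g is None or node._backward is None:
            continue
        parent_grads = node._backward(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else add(acc, pg)
    out = []
    for t in inputs:
        g = grads.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out


def backward(loss: Tensor, params: Sequence[Tensor]) -> None:
    """Populate ``p.grad`` (numpy arrays) for every parameter."""
    for p, g in zip(params, grad(loss, params)):
        p.grad = g.data


# -- layers --------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    training: bool = True

    def state_arrays(self) -> list[Array]:
        """Flat list of parameter arrays plus buffers, for checkpointing."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            arrays.extend(m.buffers())
        return arrays

    def buffers(self) -> list[Array]:
        return []

    def load_state_arrays(self, arrays: Iterable[Array]) -> None:
        it = iter(arrays)
        for p in self.parameters():
            a = next(it)
            if a.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.astype(np.float64)
        for m in self.modules():
            bufs = m.buffers()
            for b in bufs:
                a = next(it)
                b[...] = a


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(1.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv2d(Module):
    """im2col convolution over (B, C, H, W) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        scale = math.sqrt(1.0 / (c_in * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_in * kernel * kernel, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self._idx_cache: dict[tuple[int, int], tuple[Array, Array, int, int]] = {}

    def _indices(self, h: int, w: int):
        key = (h, w)
        if key not in self._idx_cache:
            k, s, p = self.kernel, self.stride, self.padding
            oh = (h + 2 * p - k) // s + 1
            ow = (w + 2 * p - k) // s + 1
            base_r = np.repeat(np.arange(k), k)
            base_c = np.tile(np.arange(k), k)
            out_r = s * np.repeat(np.arange(oh), ow)
            out_c = s * np.tile(np.arange(ow), oh)
            ri = base_r[:, None] + out_r[None, :]
            ci = base_c[:, None] + out_c[None, :]
            self._idx_cache[key] = (ri, ci, oh, ow)
        return self._idx_cache[key]

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        ri, ci, oh, ow = self._indices(h, w)
        xp = pad2d(x, self.padding)
        cols = take_patches(xp, ri, ci)  # (B, C, K2, P)
        cols = reshape(transpose(cols, (0, 3, 1, 2)), (b, oh * ow, -1))  # (B, P, C*K2)
        y = matmul(cols, self.weight) + self.bias  # (B, P, C_out)
        return transpose(reshape(y, (b, oh, ow, -1)), (0, 3, 1, 2))


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, c, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1))
        self.running_var = np.ones((1, c, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def buffers(self) -> list[Array]:
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = tmean(x, axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = tmean(mul(centred, centred), axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mean.data - self.running_mean)
            self.running_var += self.momentum * (var.data - self.running_var)
        else:
            mean = Tensor(self.running_mean)
            centred = x - mean
            var = Tensor(self.running_var)
        inv = power(var + self.eps, -0.5)
        return mul(mul(centred, inv), self.gamma) + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = tmean(x, axis=-1, keepdims=True)
        centred = x - mean
        var = tmean(mul(centred, centred), axis=-1, keepdims=True)
        return mul(mul(centred, power(var + self.eps, -0.5)), self.gamma) + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit Generator for determinism."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return mul(x, Tensor(mask))


class MultiHeadAttention(Module):
    """Scaled dot-product attention; records the last attention weights."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("hidden size must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention: Array | None = None  # (B, heads, Q, K)

    def _split(self, x: Tensor, b: int, n: int) -> Tensor:
        dh = self.dim // self.n_heads
        return transpose(reshape(x, (b, n, self.n_heads, dh)), (0, 2, 1, 3))

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        b, nq, _ = query.shape
        nk = key.shape[1]
        dh = self.dim // self.n_heads
        q = self._split(self.wq(query), b, nq)
        k = self._split(self.wk(key), b, nk)
        v = self._split(self.wv(value), b, nk)
        scores = mul(matmul(q, swap_last(k)), 1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = matmul(attn, v)  # (B, H, Nq, dh)
        out = reshape(transpose(out, (0, 2, 1, 3)), (b, nq, self.dim))
        return self.wo(out)


class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
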