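"""Minimal reverse-mode autodiff on NumPy arrays.

Gradients are themselves :class:`Tensor` graphs, so second-order terms
(e.g. a gradient penalty on a discriminator evaluated at real samples)
can be obtained by differentiating a first-order gradient again.

Only the primitives needed by the style-based networks are provided.
``leaky_relu``/``abs``/``softplus`` use locally-constant factors in their
backward pass; they are once-differentiable, which is sufficient because
the second-order path (the gradient penalty) only traverses convolutions,
matmuls and piecewise-linear activations.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "add",
    "sub",
    "mul",
    "neg",
    "matmul",
    "reshape",
    "swapaxes",
    "broadcast_to",
    "tsum",
    "tmean",
    "pow_const",
    "texp",
    "tabs",
    "sqrt",
    "leaky_relu",
    "softplus",
    "pad2d",
    "crop2d",
    "take_layer",
    "put_layer",
    "im2col",
    "col2im",
    "conv2d",
    "upsample2x",
    "downsample2x",
]


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        vjp: Callable[["Tensor"], Sequence["Tensor | None"]] | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: "Tensor | None" = None
        self._parents = tuple(parents)
        self._vjp = vjp

    # -- convenience -------------------------------------------------------
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

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_const(self, float(p))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def backward(self, create_graph: bool = False) -> None:
        """Accumulate gradients into ``.grad`` of every reachable leaf."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        leaves = [t for t in _toposort(self) if t.requires_grad and t._vjp is None]
        grads = grad(self, leaves, create_graph=create_graph, allow_unused=True)
        for leaf, g in zip(leaves, grads):
            if g is None:
                continue
            if leaf.grad is None:
                leaf.grad = g if create_graph else g.detach()
            else:
                acc = add(leaf.grad, g)
                leaf.grad = acc if create_graph else acc.detach()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    wrt: Iterable[Tensor],
    create_graph: bool = False,
    allow_unused: bool = False,
) -> list[Tensor | None]:
    """Vector-Jacobian product of a scalar ``output`` w.r.t. ``wrt`` tensors.

    With ``create_graph=True`` the returned gradients carry their own graph
    and can be differentiated again.
    """
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    wrt = list(wrt)
    order = _toposort(output)
    gmap: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(order):
        g = gmap.get(id(node))
        if g is None or node._vjp is None:
            continue
        parent_grads = node._vjp(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None:
                continue
            prev = gmap.get(id(p))
            gmap[id(p)] = pg if prev is None else add(prev, pg)
    out: list[Tensor | None] = []
    for t in wrt:
        g = gmap.get(id(t))
        if g is None:
            if not allow_unused:
                raise ValueError("a requested tensor was not reached by backward")
            out.append(None)
        else:
            out.append(g if create_graph else g.detach())
    return out


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------


def _sum_to(t: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce ``t`` (a gradient) back to ``shape`` after broadcasting."""
    if t.shape == shape:
        return t
    ndiff = t.ndim - len(shape)
    if ndiff > 0:
        t = tsum(t, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and t.shape[i] != 1)
    if axes:
        t = tsum(t, axis=axes, keepdims=True)
    if t.shape != shape:
        t = reshape(t, shape)
    return t


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _node(data, parents, vjp, req) -> Tensor:
    if req:
        return Tensor(data, requires_grad=True, parents=parents, vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = _needs(a, b)

    def vjp(g: Tensor):
        return (
            _sum_to(g, a.shape) if a.requires_grad else None,
            _sum_to(g, b.shape) if b.requires_grad else None,
        )

    return _node(a.data + b.data, (a, b), vjp, req)


def neg(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Tensor):
        return (neg(g),)

    return _node(-a.data, (a,), vjp, a.requires_grad)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(b))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = _needs(a, b)

    def vjp(g: Tensor):
        ga = _sum_to(mul(g, b), a.shape) if a.requires_grad else None
        gb = _sum_to(mul(g, a), b.shape) if b.requires_grad else None
        return ga, gb

    return _node(a.data * b.data, (a, b), vjp, req)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = _needs(a, b)

    def vjp(g: Tensor):
        ga = gb = None
        if a.requires_grad:
            ga = _sum_to(matmul(g, swapaxes(b, -1, -2)), a.shape)
        if b.requires_grad:
            gb = _sum_to(matmul(swapaxes(a, -1, -2), g), b.shape)
        return ga, gb

    return _node(a.data @ b.data, (a, b), vjp, req)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    old = a.shape

    def vjp(g: Tensor):
        return (reshape(g, old),)

    return _node(a.data.reshape(shape), (a,), vjp, a.requires_grad)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Tensor):
        return (swapaxes(g, ax1, ax2),)

    return _node(np.swapaxes(a.data, ax1, ax2), (a,), vjp, a.requires_grad)


def broadcast_to(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    old = a.shape

    def vjp(g: Tensor):
        return (_sum_to(g, old),)

    return _node(np.broadcast_to(a.data, shape).copy(), (a,), vjp, a.requires_grad)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    in_shape = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def vjp(g: Tensor):
        if not keepdims:
            kshape = tuple(
                1 if i in axes else s for i, s in enumerate(in_shape)
            )
            g = reshape(g, kshape)
        return (broadcast_to(g, in_shape),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp, a.requires_grad)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def pow_const(a: Tensor, p: float) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Tensor):
        return (mul(g, mul(pow_const(a, p - 1.0), Tensor(p))),)

    return _node(a.data**p, (a,), vjp, a.requires_grad)


def texp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g: Tensor):
        return (mul(g, Tensor(out_data)),)

    return _node(out_data, (a,), vjp, a.requires_grad)


def sqrt(a: Tensor, eps: float = 1e-12) -> Tensor:
    return pow_const(add(a, Tensor(eps)), 0.5)


def tabs(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Tensor):
        return (mul(g, Tensor(np.sign(a.data))),)

    return _node(np.abs(a.data), (a,), vjp, a.requires_grad)


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, a.data * DTYPE(alpha))

    def vjp(g: Tensor):
        factor = np.where(a.data > 0, DTYPE(1.0), DTYPE(alpha))
        return (mul(g, Tensor(factor)),)

    return _node(out, (a,), vjp, a.requires_grad)


def softplus(a: Tensor) -> Tensor:
    from scipy.special import expit

    a = as_tensor(a)
    sig = expit(a.data)

    def vjp(g: Tensor):
        return (mul(g, Tensor(sig)),)

    return _node(np.logaddexp(0.0, a.data).astype(DTYPE), (a,), vjp, a.requires_grad)


# ---------------------------------------------------------------------------
# spatial primitives (NCHW)
# ---------------------------------------------------------------------------


def pad2d(a: Tensor, p: int) -> Tensor:
    a = as_tensor(a)
    if p == 0:
        return a

    def vjp(g: Tensor):
        return (crop2d(g, p),)

    padded = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)))
    return _node(padded, (a,), vjp, a.requires_grad)


def crop2d(a: Tensor, p: int) -> Tensor:
    a = as_tensor(a)
    if p == 0:
        return a

    def vjp(g: Tensor):
        return (pad2d(g, p),)

    return _node(a.data[:, :, p:-p, p:-p], (a,), vjp, a.requires_grad)


def _im2col_np(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, kh, kw)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)


def _col2im_np(
    cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int
) -> np.ndarray:
    n, c, h, w = x_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                cols[:, :, i, j]
            )
    return out


def im2col(a: Tensor, kh: int, kw: int, stride: int = 1) -> Tensor:
    """Unfold (N,C,H,W) into (N, C*kh*kw, OH*OW); adjoint of :func:`col2im`."""
    a = as_tensor(a)
    x_shape = a.shape

    def vjp(g: Tensor):
        return (col2im(g, x_shape, kh, kw, stride),)

    return _node(_im2col_np(a.data, kh, kw, stride), (a,), vjp, a.requires_grad)


def col2im(a: Tensor, x_shape: tuple, kh: int, kw: int, stride: int = 1) -> Tensor:
    a = as_tensor(a)

    def vjp(g: Tensor):
        return (im2col(g, kh, kw, stride),)

    return _node(_col2im_np(a.data, x_shape, kh, kw, stride), (a,), vjp, a.requires_grad)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernels."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    co, ci, kh, kw = weight.shape
    if x.shape[1] != ci:
        raise ValueError(
            f"conv2d: input has {x.shape[1]} channels, weight expects {ci}"
        )
    xp = pad2d(x, padding)
    n, _, h, w = xp.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = im2col(xp, kh, kw, stride)  # (N, C*kh*kw, OH*OW)
    wmat = reshape(weight, (co, ci * kh * kw))
    out = matmul(wmat, cols)  # (N, Co, OH*OW)
    out = reshape(out, (n, co, oh, ow))
    if bias is not None:
        out = add(out, reshape(bias, (1, co, 1, 1)))
    return out


def take_layer(a: Tensor, i: int) -> Tensor:
    """Select ``a[:, i]`` from an (N, L, ...) tensor; adjoint scatters back."""
    a = as_tensor(a)
    a_shape = a.shape

    def vjp(g: Tensor):
        return (put_layer(g, a_shape, i),)

    return _node(np.ascontiguousarray(a.data[:, i]), (a,), vjp, a.requires_grad)


def put_layer(g: Tensor, full_shape: tuple, i: int) -> Tensor:
    g = as_tensor(g)

    def vjp(gg: Tensor):
        return (take_layer(gg, i),)

    out = np.zeros(full_shape, dtype=DTYPE)
    out[:, i] = g.data
    return _node(out, (g,), vjp, g.requires_grad)


def upsample2x(a: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling; adjoint is 2x2 sum pooling."""
    a = as_tensor(a)
    n, c, h, w = a.shape

    def vjp(g: Tensor):
        gr = reshape(g, (n, c, h, 2, w, 2))
        return (tsum(gr, axis=(3, 5)),)

    up = np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3)
    return _node(up, (a,), vjp, a.requires_grad)


def downsample2x(a: Tensor) -> Tensor:
    """2x2 average pooling."""
    a = as_tensor(a)
    n, c, h, w = a.shape
    return tmean(reshape(a, (n, c, h // 2, 2, w // 2, 2)), axis=(3, 5))
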