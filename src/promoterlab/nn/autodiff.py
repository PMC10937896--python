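"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-free autograd: each :class:`Tensor` records its parents and a
vector-Jacobian product (VJP) closure.  VJPs are themselves expressed in
traced tensor operations, so gradients of gradients work — this is what the
Wasserstein-GAN gradient penalty and latent-space gradient ascent require.

Everything is float64.  The engine is deliberately small: only the
operations the sequence models in this package need are provided.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "matmul",
    "concatenate",
    "relu",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "softmax",
    "log_softmax",
    "take",
    "broadcast_to",
    "reshape",
    "swapaxes",
    "sqrt",
]


class Tensor:
    """A numpy array with optional gradient tracking."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjp = vjp
        self.requires_grad = bool(requires_grad)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


def _track(*tensors):
    return any(t.requires_grad for t in tensors)


def _make(data, parents, vjp):
    if _track(*parents):
        return Tensor(data, parents=tuple(parents), vjp=vjp, requires_grad=True)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum a cotangent down to ``shape`` (reverse of numpy broadcasting)."""
    while g.data.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(
        i for i, (gs, ts) in enumerate(zip(g.data.shape, shape)) if ts == 1 and gs != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# -- arithmetic --------------------------------------------------------


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(a.data + b.data, (a, b), vjp)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return _make(a.data * b.data, (a, b), vjp)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(mul(mul(g, -1.0), div(a, mul(b, b))), b.shape)
        return ga, gb

    return _make(a.data / b.data, (a, b), vjp)


def power(a, c: float):
    a = as_tensor(a)
    c = float(c)

    def vjp(g):
        return (mul(g, mul(power(a, c - 1.0), c)),)

    return _make(a.data**c, (a,), vjp)


def sqrt(a):
    return power(a, 0.5)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.shape)
        gb = _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.shape)
        return ga, gb

    return _make(np.matmul(a.data, b.data), (a, b), vjp)


# -- reductions / shape ------------------------------------------------


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            gg = broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.ndim for ax in axes)
            if not keepdims:
                kshape = tuple(
                    1 if i in axes else s for i, s in enumerate(a.shape)
                )
                g = reshape(g, kshape)
            gg = broadcast_to(g, a.shape)
        return (gg,)

    return _make(out, (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)
    orig = a.shape

    def vjp(g):
        return (reshape(g, orig),)

    return _make(a.data.reshape(shape), (a,), vjp)


def broadcast_to(a, shape):
    a = as_tensor(a)
    orig = a.shape

    def vjp(g):
        return (_unbroadcast(g, orig),)

    return _make(np.broadcast_to(a.data, shape), (a,), vjp)


def swapaxes(a, ax1, ax2):
    a = as_tensor(a)

    def vjp(g):
        return (swapaxes(g, ax1, ax2),)

    return _make(np.swapaxes(a.data, ax1, ax2), (a,), vjp)


def getitem(a, idx):
    a = as_tensor(a)
    shape = a.shape

    def vjp(g):
        return (_unslice(g, idx, shape),)

    return _make(a.data[idx], (a,), vjp)


def _unslice(g, idx, shape):
    g = as_tensor(g)

    def vjp(gg):
        return (getitem(gg, idx),)

    out = np.zeros(shape, dtype=np.float64)
    out[idx] = g.data
    return _make(out, (g,), vjp)


def take(a, indices, axis):
    """Gather along ``axis`` with a constant integer index array."""
    a = as_tensor(a)
    indices = np.asarray(indices, dtype=np.intp)
    shape = a.shape

    def vjp(g):
        return (scatter_add(g, indices, axis, shape),)

    return _make(np.take(a.data, indices, axis=axis), (a,), vjp)


def scatter_add(g, indices, axis, shape):
    g = as_tensor(g)
    indices = np.asarray(indices, dtype=np.intp)

    def vjp(gg):
        return (take(gg, indices, axis),)

    out = np.zeros(shape, dtype=np.float64)
    # accumulate duplicate indices along `axis`
    moved = np.moveaxis(out, axis, 0)
    flat_idx = indices.reshape(-1)
    gdat = np.moveaxis(
        g.data, list(range(axis, axis + indices.ndim)), list(range(indices.ndim))
    )
    gdat = gdat.reshape((flat_idx.size,) + moved.shape[1:])
    np.add.at(moved, flat_idx, gdat)
    return _make(out, (g,), vjp)


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(start), int(stop))
            outs.append(getitem(g, tuple(idx)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


# -- nonlinearities ----------------------------------------------------


def relu(a):
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float64)

    def vjp(g):
        return (mul(g, mask),)

    return _make(a.data * mask, (a,), vjp)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def vjp(g):
        # d tanh = 1 - tanh^2; re-expressed with traced ops on `a` so that
        # second derivatives propagate
        y = tanh(a)
        return (mul(g, add(1.0, mul(mul(y, y), -1.0))),)

    return _make(out_data, (a,), vjp)


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def vjp(g):
        y = sigmoid(a)
        return (mul(g, mul(y, add(1.0, mul(y, -1.0)))),)

    return _make(out, (a,), vjp)


def exp(a):
    a = as_tensor(a)

    def vjp(g):
        return (mul(g, exp(a)),)

    return _make(np.exp(np.clip(a.data, -700, 700)), (a,), vjp)


def log(a):
    a = as_tensor(a)

    def vjp(g):
        return (div(g, a),)

    return _make(np.log(a.data), (a,), vjp)


def softmax(a, axis=-1):
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant stabiliser
    e = exp(a - shift)
    return div(e, tsum(e, axis=axis, keepdims=True))


def log_softmax(a, axis=-1):
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)
    s = a - shift
    return s - log(tsum(exp(s), axis=axis, keepdims=True))


# -- backward pass -----------------------------------------------------


def _toposort(out: Tensor):
    """Iterative depth-first post-order over grad-requiring nodes."""
    order = []
    visited = set()
    stack = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))
    return order


def grad(output: Tensor, wrt) -> list:
    """Gradients of a scalar ``output`` with respect to each tensor in ``wrt``.

    Returned gradients are traced tensors, so they can themselves be
    differentiated (e.g. for gradient penalties).
    """
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(_toposort(output)):
        g = grads.pop(id(node), None)
        if g is None or node.vjp is None:
            if g is not None:
                grads[id(node)] = g
            continue
        keep = any(id(node) == id(w) for w in wrt_list)
        if keep:
            grads[id(node)] = g
        for parent, pg in zip(node.parents, node.vjp(g)):
            if not parent.requires_grad:
                continue
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)
    out = [
        grads.get(id(w), Tensor(np.zeros_like(w.data))) for w in wrt_list
    ]
    return out[0] if single else out
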