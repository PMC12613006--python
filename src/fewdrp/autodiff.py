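"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with the tape that produced
it.  Every vector-Jacobian product is itself expressed in terms of Tensor
operations, so the output of :func:`grad` is again differentiable — gradients
of gradients work to arbitrary order.  This is what makes exact second-order
meta-gradients (backpropagation through an inner SGD step) possible.

Only the operations the model family needs are provided: broadcasting
arithmetic, batched ``matmul``, elementwise nonlinearities, reductions,
shape manipulation, gather/scatter and basic slicing.  float64 throughout.
"""

from __future__ import annotations

import numpy as np

_F64 = np.float64

__all__ = [
    "Tensor", "as_tensor", "grad",
    "exp", "log", "tanh", "relu", "sqrt", "absolute", "sigmoid",
    "tsum", "tmean", "reshape", "transpose", "swap_last", "concat",
    "take", "broadcast_to", "softmax", "detach",
]


class Tensor:
    """An ndarray node in a differentiation tape.

    Leaf tensors have no parents; non-leaves carry one vjp closure per
    parent, each mapping the upstream cotangent (a Tensor) to the parent's
    cotangent contribution (also a Tensor).
    """

    __slots__ = ("data", "parents", "vjps")

    def __init__(self, data, parents=(), vjps=()):
        if type(data) is np.ndarray and data.dtype == _F64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=_F64)
        self.parents = parents
        self.vjps = vjps

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, leaf={not self.parents})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def detach(x: Tensor) -> Tensor:
    """Cut the tape: return a leaf with the same values."""
    return Tensor(x.data)


# ----------------------------------------------------------------------
# broadcasting helper
# ----------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum cotangent ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ----------------------------------------------------------------------
# arithmetic
# ----------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, (a, b),
                  (lambda g: _unbroadcast(g, a.shape),
                   lambda g: _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data - b.data, (a, b),
                  (lambda g: _unbroadcast(g, a.shape),
                   lambda g: _unbroadcast(neg(g), b.shape)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data, (a, b),
                  (lambda g: _unbroadcast(mul(g, b), a.shape),
                   lambda g: _unbroadcast(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data / b.data, (a, b),
                  (lambda g: _unbroadcast(div(g, b), a.shape),
                   lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)))


def power(a: Tensor, p) -> Tensor:
    p = float(p)
    return Tensor(a.data ** p, (a,),
                  (lambda g: mul(g, mul(Tensor(p), power(a, p - 1.0))),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    # 2-D or batched (>=3-D) operands only; numpy broadcasting rules apply.
    return Tensor(np.matmul(a.data, b.data), (a, b),
                  (lambda g: _unbroadcast(matmul(g, swap_last(b)), a.shape),
                   lambda g: _unbroadcast(matmul(swap_last(a), g), b.shape)))


def spmm(sp, x: Tensor) -> Tensor:
    """Multiply a *constant* scipy sparse matrix [n, n] into ``x``.

    ``x`` may be [n, h] or batched [S, n, h].  The matrix is a fixed graph
    operator (no gradient); the vjp multiplies by its transpose.
    """
    def apply(mat, arr):
        if arr.ndim == 2:
            return mat @ arr
        S, n, h = arr.shape
        out = mat @ arr.transpose(1, 0, 2).reshape(n, S * h)
        return out.reshape(n, S, h).transpose(1, 0, 2)

    spT = sp.T.tocsr()
    return Tensor(apply(sp, x.data), (x,),
                  (lambda g: spmm(spT, g),))


# ----------------------------------------------------------------------
# elementwise nonlinearities
# ----------------------------------------------------------------------

def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), (a,), ())
    out.vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), (a,), (lambda g: div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), (a,), ())
    out.vjps = (lambda g: div(g, mul(Tensor(2.0), out)),)
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.data), (a,), ())
    out.vjps = (lambda g: mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-a.data)), (a,), ())
    out.vjps = (lambda g: mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(a.data * mask.data, (a,), (lambda g: mul(g, mask),))


def absolute(a: Tensor) -> Tensor:
    sign = Tensor(np.sign(a.data))
    return Tensor(np.abs(a.data), (a,), (lambda g: mul(g, sign),))


# ----------------------------------------------------------------------
# reductions and shape ops
# ----------------------------------------------------------------------

def _keepdims_shape(shape, axis):
    if axis is None:
        return (1,) * len(shape)
    axes = axis if isinstance(axis, tuple) else (axis,)
    axes = tuple(a % len(shape) for a in axes)
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    kd_shape = _keepdims_shape(a.shape, axis)

    def vjp(g):
        return broadcast_to(reshape(g, kd_shape), a.shape)

    return Tensor(np.sum(a.data, axis=axis, keepdims=keepdims), (a,), (vjp,))


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        denom = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        denom = int(np.prod([a.shape[ax] for ax in axes]))
    return div(tsum(a, axis=axis, keepdims=keepdims), Tensor(float(denom)))


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(np.broadcast_to(a.data, shape), (a,),
                  (lambda g: _unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(sorted(range(len(axes)), key=axes.__getitem__))
    return Tensor(np.transpose(a.data, axes), (a,), (lambda g: transpose(g, inv),))


def swap_last(a: Tensor) -> Tensor:
    """Transpose the last two axes (any rank >= 2)."""
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def concat(tensors, axis=0) -> Tensor:
    tensors = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(idx))
        return vjp

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tensors, tuple(make_vjp(i) for i in range(len(tensors))))


def getitem(a: Tensor, idx) -> Tensor:
    return Tensor(a.data[idx], (a,), (lambda g: _put(g, idx, a.shape),))


def _put(g: Tensor, idx, shape) -> Tensor:
    """Scatter ``g`` into a zero array of ``shape`` at ``idx`` (adjoint of getitem)."""
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return Tensor(out, (g,), (lambda h: getitem(h, idx),))


def take(a: Tensor, indices: np.ndarray) -> Tensor:
    """Integer-array gather along axis 0 (embedding lookup)."""
    indices = np.asarray(indices, dtype=np.intp)
    return Tensor(a.data[indices], (a,), (lambda g: _scatter(g, indices, a.shape),))


def _scatter(g: Tensor, indices: np.ndarray, shape) -> Tensor:
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, indices, g.data)
    return Tensor(out, (g,), (lambda h: take(h, indices),))


# ----------------------------------------------------------------------
# fused ops: one tape node each, with vjps still expressed in tensor ops
# so higher-order differentiation stays exact
# ----------------------------------------------------------------------

def softmax(a: Tensor, axis=-1) -> Tensor:
    e = np.exp(a.data - np.max(a.data, axis=axis, keepdims=True))
    out = Tensor(e / e.sum(axis=axis, keepdims=True), (a,), ())
    out.vjps = (lambda g: mul(out, sub(g, tsum(mul(g, out), axis=axis,
                                               keepdims=True))),)
    return out


def layer_norm_core(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance (no affine)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    out = Tensor(xc / np.sqrt(var + eps), (x,), ())

    def vjp(g):
        # rebuild the differentiable pieces so grad-of-grad stays exact
        mu_t = tmean(x, axis=-1, keepdims=True)
        xc_t = sub(x, mu_t)
        var_t = tmean(mul(xc_t, xc_t), axis=-1, keepdims=True)
        inv_t = power(add(var_t, Tensor(eps)), -0.5)
        xhat = mul(xc_t, inv_t)
        m1 = tmean(g, axis=-1, keepdims=True)
        m2 = tmean(mul(g, xhat), axis=-1, keepdims=True)
        return mul(sub(sub(g, m1), mul(xhat, m2)), inv_t)

    out.vjps = (vjp,)
    return out


# ----------------------------------------------------------------------
# reverse-mode driver
# ----------------------------------------------------------------------

def _toposort(root: Tensor):
    order, visited, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in visited:
                stack.append((p, False))
    return order  # parents before children


def grad(out: Tensor, wrt, grad_out: Tensor | None = None):
    """Cotangents of ``out`` with respect to each tensor in ``wrt``.

    ``out`` must be scalar unless ``grad_out`` supplies the seed cotangent.
    The returned tensors stay on the tape, so differentiating through them
    again yields exact higher-order derivatives.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if grad_out is None:
        if out.size != 1:
            raise ValueError("grad of a non-scalar requires grad_out")
        grad_out = Tensor(np.ones_like(out.data))

    order = _toposort(out)
    wrt_ids = {id(w) for w in wrt_list}
    # mark nodes whose value influences some wrt leaf (reachability upstream)
    needed: set[int] = set()
    for node in order:  # parents precede children
        if id(node) in wrt_ids or any(id(p) in needed for p in node.parents):
            needed.add(id(node))

    grads: dict[int, Tensor] = {id(out): grad_out}
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for p, vjp in zip(node.parents, node.vjps):
            if id(p) not in needed:
                continue
            contrib = vjp(g)
            acc = grads.get(id(p))
            grads[id(p)] = contrib if acc is None else add(acc, contrib)
        if id(node) in wrt_ids:
            grads[id(node)] = g  # restore for collection

    results = []
    for w in wrt_list:
        gw = grads.get(id(w))
        results.append(gw if gw is not None else Tensor(np.zeros_like(w.data)))
    return results[0] if single else results
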