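"""Reverse-mode automatic differentiation on numpy arrays.

The WGAN-GP objective needs gradients of the critic with respect to its
*input* (the interpolated sample), and then gradients of a function of that
gradient's norm with respect to the critic's *parameters*.  Every vector-
Jacobian product here is therefore itself expressed in terms of the same
primitive operations, so a gradient computed with ``create_graph=True`` is a
differentiable node and second-order ("double") backprop works out of the box.

Only the primitives the signal models need are implemented; everything is
float64 so arithmetic oracles in the test-suite hold to tight tolerances.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference / plain numerics)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents: tuple = ()
        self.vjp = None

    # -- construction of non-leaf nodes -------------------------------------
    @staticmethod
    def _make(data, parents, vjp):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out.parents = tuple(parents)
            out.vjp = vjp
        return out

    # -- conveniences --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, s):
        return power(self, s)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)


# ---------------------------------------------------------------------------
# broadcasting helper
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor._make(a.data + b.data, (a, b), vjp)


def neg(a: Tensor) -> Tensor:
    return Tensor._make(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return Tensor._make(a.data * b.data, (a, b), vjp)


def div(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)
        return ga, gb

    return Tensor._make(a.data / b.data, (a, b), vjp)


def power(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def vjp(g):
        return (mul(g, mul(Tensor(np.array(s)), power(a, s - 1.0))),)

    return Tensor._make(a.data**s, (a,), vjp)


def texp(a: Tensor) -> Tensor:
    out = Tensor._make(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, out),)
    return out


def tlog(a: Tensor) -> Tensor:
    return Tensor._make(np.log(a.data), (a,), lambda g: (div(g, a),))


def tanh(a: Tensor) -> Tensor:
    out = Tensor._make(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, add(Tensor(np.array(1.0)), neg(mul(out, out)))),)
    return out


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor._make(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def tabs(a: Tensor) -> Tensor:
    sign = Tensor(np.sign(a.data))
    return Tensor._make(np.abs(a.data), (a,), lambda g: (mul(g, sign),))


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; sub-gradient routes to the (first) argmax."""
    out_data = a.data.max(axis=axis, keepdims=True)
    mask_np = (a.data == out_data).astype(np.float64)
    mask_np /= mask_np.sum(axis=axis, keepdims=True)
    mask = Tensor(mask_np)

    def vjp(g):
        gk = g if keepdims else reshape(g, out_data.shape)
        return (mul(broadcast_to(gk, a.shape), mask),)

    return Tensor._make(out_data if keepdims else np.squeeze(out_data, axis=axis), (a,), vjp)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if isinstance(axis, int):
        axis = (axis,)

    def vjp(g):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * a.ndim), a.shape),)
        if not keepdims:
            kshape = list(a.shape)
            for ax in axis:
                kshape[ax % a.ndim] = 1
            g = reshape(g, tuple(kshape))
        return (broadcast_to(g, a.shape),)

    return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.array(1.0 / n)))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return Tensor._make(
        np.broadcast_to(a.data, shape), (a,), lambda g: (_unbroadcast(g, a.shape),)
    )


def reshape(a: Tensor, shape: tuple) -> Tensor:
    return Tensor._make(
        a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),)
    )


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return Tensor._make(
        np.transpose(a.data, axes), (a,), lambda g: (transpose(g, inv),)
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        if b.ndim == 1:
            # (..., n, k) @ (k,) -> (..., n)
            ga = mul(reshape(g, g.shape + (1,)), b)
            gb_full = mul(reshape(g, g.shape + (1,)), a)
            gb = tsum(gb_full, axis=tuple(range(gb_full.ndim - 1)))
            return _unbroadcast(ga, a.shape), gb
        if a.ndim == 1:
            raise NotImplementedError("1-D left operand not used by the models")
        bt = transpose(b, tuple(range(b.ndim - 2)) + (b.ndim - 1, b.ndim - 2))
        at = transpose(a, tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2))
        return _unbroadcast(matmul(g, bt), a.shape), _unbroadcast(matmul(at, g), b.shape)

    return Tensor._make(a.data @ b.data, (a, b), vjp)


def getitem(a: Tensor, key) -> Tensor:
    return Tensor._make(
        a.data[key], (a,), lambda g: (scatter_slice(g, key, a.shape),)
    )


def scatter_slice(g: Tensor, key, shape: tuple) -> Tensor:
    """Adjoint of basic slicing: embed ``g`` into zeros of ``shape``."""
    def fwd(gd):
        out = np.zeros(shape, dtype=np.float64)
        out[key] = gd
        return out

    return Tensor._make(fwd(g.data), (g,), lambda gg: (getitem(gg, key),))


def take(a: Tensor, indices: np.ndarray, axis: int) -> Tensor:
    indices = np.asarray(indices)
    return Tensor._make(
        np.take(a.data, indices, axis=axis),
        (a,),
        lambda g: (take_adjoint(g, indices, axis, a.shape),),
    )


def take_adjoint(g: Tensor, indices: np.ndarray, axis: int, shape: tuple) -> Tensor:
    """Adjoint of ``take``: scatter-add rows of ``g`` back into ``shape``."""
    def fwd(gd):
        out = np.zeros(shape, dtype=np.float64)
        moved = np.moveaxis(out, axis, 0)
        gmoved = np.moveaxis(
            gd.reshape(shape[:axis] + indices.shape + shape[axis + 1:]),
            tuple(range(axis, axis + indices.ndim)),
            tuple(range(indices.ndim)),
        )
        np.add.at(moved, indices.ravel(),
                  gmoved.reshape((-1,) + moved.shape[1:]))
        return out

    return Tensor._make(fwd(g.data), (g,), lambda gg: (take(gg, indices, axis),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = tuple(slice(None) for _ in range(axis % t.ndim)) + (slice(int(lo), int(hi)),)
            outs.append(getitem(g, key))
        return tuple(outs)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


# ---------------------------------------------------------------------------
# composed elementwise nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    return div(Tensor(np.array(1.0)), add(Tensor(np.array(1.0)), texp(neg(a))))


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(a: Tensor) -> Tensor:
    inner = mul(Tensor(np.array(_GELU_C)), add(a, mul(Tensor(np.array(0.044715)), power(a, 3.0))))
    return mul(mul(Tensor(np.array(0.5)), a), add(Tensor(np.array(1.0)), tanh(inner)))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = texp(shifted)
    return div(e, tsum(e, axis=axis, keepdims=True))


def logsigmoid(a: Tensor) -> Tensor:
    # numerically stable log sigmoid: min(a, 0) - log1p(exp(-|a|)),
    # with min(a, 0) = (a - |a|)/2 so the kink stays differentiable
    m = mul(add(a, neg(tabs(a))), Tensor(np.array(0.5)))
    return add(m, neg(tlog(add(texp(neg(tabs(a))), Tensor(np.array(1.0))))))


# ---------------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False, grad_output=None):
    """Gradients of scalar (or seeded) ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors are themselves nodes of a
    differentiable graph (needed for the gradient penalty).  Otherwise the
    traversed graph is released afterwards: the vjp closures form reference
    cycles (a node's closure captures the node), and dropping them here keeps
    long training loops at constant memory without waiting for the cycle
    collector.
    """
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads = {id(output): grad_output}

    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = bool(create_graph)
    topo = _topo(output)
    try:
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node.vjp is None:
                if g is not None:
                    grads[id(node)] = g
                continue
            parent_grads = node.vjp(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
            if any(node is t for t in inputs):
                grads[id(node)] = g
    finally:
        _GRAD_ENABLED = prev

    out = [grads.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]
    if not create_graph:
        for node in topo:
            node.vjp = None
            node.parents = ()
    return out[0] if single else out
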