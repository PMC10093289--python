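"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation,
a closure that propagates the output gradient to the operation's inputs.
``Tensor.backward()`` runs the closures in reverse topological order.
Only the operations needed by the segmentation networks and their losses
are implemented; convolution and normalisation primitives live in
:mod:`adverseg.nn.layers` and build nodes through :func:`make_node`.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # numpy scalar keeps its dtype
            self.data = np.asarray(data)
        else:  # python scalars / lists default to float32
            self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate_grad(self, g: np.ndarray) -> None:
        dtype = np.float64 if self.data.dtype == np.float64 else np.float32
        if self.grad is None:
            # copy: g may be a view into another tensor's gradient buffer
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)) and not isinstance(other, bool):
            return add(self, -other)
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)) and not isinstance(other, bool):
            return add(-self, other)
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def abs(self):
        return tabs(self)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def make_node(data, parents, backward) -> Tensor:
    """Create an output tensor; attach the graph only when grads are live."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._backward is not None
                             for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- primitive ops -----------------------------------------------------------

def _is_py_scalar(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def add(a, b) -> Tensor:
    if _is_py_scalar(b):  # python scalars keep the array dtype exactly
        a = _wrap(a)
        out_data = a.data + b

        def backward_s(g):
            a.accumulate_grad(_unbroadcast(g, a.data.shape))

        return make_node(out_data, (a,), backward_s)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._backward is not None:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return make_node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    if _is_py_scalar(b):
        a = _wrap(a)
        out_data = a.data * b

        def backward_s(g):
            a.accumulate_grad(_unbroadcast(g * b, a.data.shape))

        return make_node(out_data, (a,), backward_s)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._backward is not None:
            b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return make_node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    if _is_py_scalar(b):
        return mul(a, 1.0 / b) if b in (1.0, -1.0, 2.0) else _div_scalar(a, b)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a.accumulate_grad(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad or b._backward is not None:
            b.accumulate_grad(_unbroadcast(-g * out_data / b.data, b.data.shape))

    return make_node(out_data, (a, b), backward)


def _div_scalar(a, b: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data / b

    def backward(g):
        a.accumulate_grad(_unbroadcast(g / b, a.data.shape))

    return make_node(out_data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(g, axis)
        a.accumulate_grad(np.broadcast_to(gg, a.data.shape).copy())

    return make_node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tabs(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.abs(a.data)

    def backward(g):
        a.accumulate_grad(g * np.sign(a.data))

    return make_node(out_data, (a,), backward)


def tlog(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        a.accumulate_grad(g / a.data)

    return make_node(out_data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a.accumulate_grad(g.reshape(a.data.shape))

    return make_node(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out_data = out_data.astype(x.dtype, copy=False)

    def backward(g):
        a.accumulate_grad(g * out_data * (1.0 - out_data))

    return make_node(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a.accumulate_grad(g * (a.data > 0))

    return make_node(out_data, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    a = _wrap(a)
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def backward(g):
        a.accumulate_grad(g * np.where(a.data > 0, 1.0, slope).astype(g.dtype))

    return make_node(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._backward is not None:
            a.accumulate_grad(g @ b.data.T)
        if b.requires_grad or b._backward is not None:
            b.accumulate_grad(a.data.T @ g)

    return make_node(out_data, (a, b), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    out_data = np.ascontiguousarray(a.data.transpose(axes))
    inverse = tuple(np.argsort(axes))

    def backward(g):
        a.accumulate_grad(g.transpose(inverse))

    return make_node(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad or t._backward is not None:
                t.accumulate_grad(p)

    return make_node(out_data, tuple(tensors), backward)
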