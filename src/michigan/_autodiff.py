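"""Reverse-mode automatic differentiation on numpy arrays.

Small tape-based engine used by the neural-network models in this package.
Vector-Jacobian products are themselves composed of :class:`Tensor`
operations, so gradients are differentiable: ``grad(..., create_graph=True)``
supports the double backpropagation required by the Wasserstein-GAN gradient
penalty (a loss containing the norm of a gradient).

Only the operations the models need are implemented; everything works on
float64 arrays with numpy broadcasting semantics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "grad", "no_grad", "concat", "use_dtype"]

_GRAD_ENABLED = True

#: default floating dtype for all Tensor data. float32 is the training
#: default; switch to float64 (``use_dtype``) when checking gradients
#: against finite differences.
DTYPE = np.float32


class use_dtype:
    """Context manager temporarily changing the engine's floating dtype."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global DTYPE
        self._prev = DTYPE
        DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global DTYPE
        DTYPE = self._prev
        return False


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(g: "Tensor", shape: tuple) -> "Tensor":
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    # sum leading axes added by broadcasting
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "requires_grad", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self._vjps = ()  # tuple of (parent, vjp_fn)

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, vjps):
        out = Tensor(data)
        if _GRAD_ENABLED:
            vjps = tuple((p, fn) for p, fn in vjps if p.requires_grad or p._vjps)
            if vjps:
                out._vjps = vjps
                out.requires_grad = True
        return out

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other, self.shape)),
                (other, lambda g: _unbroadcast(g * self, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self**-1.0

    def __pow__(self, p: float):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents supported")
        return Tensor._make(
            self.data**p,
            [(self, lambda g: g * (p * self ** (p - 1.0)))],
        )

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data @ other.data,
            [
                (self, lambda g: g @ other.T),
                (other, lambda g: self.T @ g),
            ],
        )

    @property
    def T(self) -> "Tensor":
        return Tensor._make(self.data.T, [(self, lambda g: g.T)])

    # -- elementwise functions ----------------------------------------------
    def exp(self) -> "Tensor":
        out_ref = []
        out = Tensor._make(np.exp(self.data),
                           [(self, lambda g: g * out_ref[0])])
        out_ref.append(out)
        return out

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self)])

    def sqrt(self) -> "Tensor":
        return self**0.5

    def tanh(self) -> "Tensor":
        out_ref = []
        out = Tensor._make(
            np.tanh(self.data),
            [(self, lambda g: g * (1.0 - out_ref[0] * out_ref[0]))])
        out_ref.append(out)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = Tensor(np.where(self.data > 0, 1.0, slope))
        return self * mask

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through inside [lo, hi], 0 outside."""
        inside = Tensor(((self.data > lo) & (self.data < hi)).astype(float))
        edges = Tensor(np.clip(self.data, lo, hi) * (1.0 - inside.data))
        return self * inside + edges

    def sigmoid(self) -> "Tensor":
        out_ref = []
        out = Tensor._make(
            1.0 / (1.0 + np.exp(-self.data)),
            [(self, lambda g: g * out_ref[0] * (1.0 - out_ref[0]))])
        out_ref.append(out)
        return out

    # -- reductions / shaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdims_shape(self.shape, axis))
            return gd.broadcast_to(self.shape)

        return Tensor._make(data, [(self, vjp)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else _axis_size(self.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def broadcast_to(self, shape) -> "Tensor":
        if self.shape == tuple(shape):
            return self
        return Tensor._make(
            np.broadcast_to(self.data, shape),
            [(self, lambda g: _unbroadcast(g, self.shape))],
        )

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), [(self, lambda g: g.reshape(old))]
        )

    def __getitem__(self, idx):
        def vjp(g):
            buf = np.zeros(self.shape)
            # scatter-add of upstream gradient back into the source slot
            np.add.at(buf, idx, g.data)
            out = Tensor(buf)
            if g.requires_grad or g._vjps:
                out = Tensor._make(buf, [(g, lambda gg: gg[idx])])
            return out

        return Tensor._make(self.data[idx], [(self, vjp)])


def _keepdims_shape(shape, axis):
    if isinstance(axis, int):
        axis = (axis,)
    axis = tuple(a % len(shape) for a in axis)
    return tuple(1 if i in axis else s for i, s in enumerate(shape))


def _axis_size(shape, axis):
    if isinstance(axis, int):
        axis = (axis,)
    n = 1
    for a in axis:
        n *= shape[a % len(shape)]
    return n


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis` (differentiable)."""
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    vjps = []
    start = 0
    for t in tensors:
        n = t.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + n)
        sl = tuple(sl)
        vjps.append((t, lambda g, sl=sl: g[sl]))
        start += n
    return Tensor._make(data, vjps)


def _topo_order(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._vjps:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of scalar `output` w.r.t. each tensor in `inputs`.

    With ``create_graph=True`` the returned gradients carry their own tape and
    may be differentiated again (double backprop).
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output; reduce first")
    seed = Tensor(np.ones(output.shape))
    grads: dict[int, Tensor] = {id(output): seed}
    order = _topo_order(output)

    ctx = no_grad() if not create_graph else _NullCtx()
    with ctx:
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None:
                continue
            for parent, vjp in node._vjps:
                contrib = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contrib if prev is None else prev + contrib

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape))
        out.append(g)
    return out


class _NullCtx:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
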