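"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective of a penalised Wasserstein critic contains the input
gradient of the critic itself (the Lipschitz penalty term), so differentiating
the full loss with respect to the network weights requires grad-of-grad.  The
vector-Jacobian products below are therefore expressed in terms of ``Tensor``
operations: calling :func:`grad` with ``create_graph=True`` yields gradients
that are themselves differentiable nodes.

Only the operations the fully-connected SELU networks need are provided
(elementwise arithmetic, matmul, exp/log/sqrt, reductions, SELU).  Shapes
broadcast by numpy rules; backward passes un-broadcast by summation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "grad", "selu"]

# SELU constants (Klambauer et al. self-normalising networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjps=()):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjps = _vjps

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _ensure_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other),
                     _vjps=(lambda g: _unbroadcast(g, self.shape),
                            lambda g: _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-_ensure_tensor(other))

    def __rsub__(self, other):
        return _ensure_tensor(other) + (-self)

    def __mul__(self, other):
        other = _ensure_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other),
                     _vjps=(lambda g: _unbroadcast(g * other, self.shape),
                            lambda g: _unbroadcast(g * self, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _ensure_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _ensure_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        e = float(exponent)
        out = Tensor(self.data ** e, _parents=(self,),
                     _vjps=(lambda g: g * (e * self ** (e - 1.0)),))
        return out

    def __matmul__(self, other):
        other = _ensure_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other),
                     _vjps=(lambda g: g @ other.T, lambda g: self.T @ g))
        return out

    @property
    def T(self) -> "Tensor":
        return Tensor(self.data.T, _parents=(self,), _vjps=(lambda g: g.T,))

    # -- transcendental -------------------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,), _vjps=(lambda g: g * out,))
        return out

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), _parents=(self,),
                      _vjps=(lambda g: g * self ** -1.0,))

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdims_shape(shape, axis))
            return gd.broadcast_to(shape)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _vjps=(vjp,))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in _norm_axes(axis, self.ndim)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, shape) -> "Tensor":
        old = self.shape
        return Tensor(self.data.reshape(shape), _parents=(self,),
                      _vjps=(lambda g: g.reshape(old),))

    def broadcast_to(self, shape) -> "Tensor":
        return Tensor(np.broadcast_to(self.data, shape), _parents=(self,),
                      _vjps=(lambda g: _unbroadcast(g, self.shape),))


def _ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if np.isscalar(axis):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _keepdims_shape(shape, axis):
    axes = _norm_axes(axis, len(shape))
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def selu(x: Tensor) -> Tensor:
    """Scaled exponential linear unit with a graph-differentiable backward."""
    x = _ensure_tensor(x)
    pos = (x.data > 0).astype(np.float64)
    y = _SELU_SCALE * np.where(pos > 0, x.data, _SELU_ALPHA * (np.exp(x.data) - 1.0))

    def vjp(g):
        # derivative: scale for x>0, scale*alpha*exp(x) otherwise; the mask is
        # piecewise-constant so it is treated as data, keeping exp(x) on the tape
        neg = 1.0 - pos
        return g * (Tensor(pos * _SELU_SCALE)
                    + Tensor(neg * _SELU_SCALE * _SELU_ALPHA) * x.exp())

    return Tensor(y, _parents=(x,), _vjps=(vjp,))


def _topo_order(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    return order  # children before parents


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of a scalar (or seeded) ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors stay on the tape, so a
    second :func:`grad` call can differentiate through them.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("grad of a non-scalar output needs grad_output")
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): _ensure_tensor(grad_output)}

    for node in reversed(_topo_order(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            if not create_graph:
                pg = pg.detach()
            if id(parent) in grads:
                grads[id(parent)] = grads[id(parent)] + pg
            else:
                grads[id(parent)] = pg
        if id(node) in (id(t) for t in inputs):
            grads[id(node)] = g  # keep leaf grads

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out[0] if single else out
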