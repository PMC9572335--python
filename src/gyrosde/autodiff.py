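"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

The package's networks are small (two-layer MLPs and a two-layer,
single-head transformer), so a compact tape-based engine is sufficient:
every operation builds a node recording its parents and a backward rule,
and :meth:`Tensor.backward` runs reverse topological accumulation.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape (:func:`_unbroadcast`).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient slot and a backward rule.

    Parameters created with ``requires_grad=True`` accumulate gradients in
    ``.grad`` during :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- graph construction --------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def backward(g, a=self):
            return (g * p * a.data ** (p - 1),)

        return self._node(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            # promote 1-D operands to matrices so one rule covers all cases
            ad, bd, gd = a.data, b.data, g
            a1, b1 = ad.ndim == 1, bd.ndim == 1
            if a1:
                ad, gd = ad[None, :], np.expand_dims(gd, -2)
            if b1:
                bd, gd = bd[:, None], np.expand_dims(gd, -1)
            ga = gd @ np.swapaxes(bd, -1, -2)
            gb = np.swapaxes(ad, -1, -2) @ gd
            if a1:
                ga = np.squeeze(ga, -2)
            if b1:
                gb = np.squeeze(gb, -1)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._node(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, d=out_data):
            return (g * d,)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            return (g / a.data,)

        return self._node(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, d=out_data):
            return (g * (1.0 - d * d),)

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, d=out_data):
            return (g * d * (1.0 - d),)

        return self._node(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, s=sig):
            return (g * s,)

        return self._node(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions & reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g, orig=orig):
            return (g.reshape(orig),)

        return self._node(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g, a=a, b=b):
            return (np.swapaxes(g, a, b),)

        return self._node(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._node(self.data[idx], (self,), backward)

    # -- softmax (stable, last axis) -----------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g, s=out_data, axis=axis):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._node(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
        # flush any leaves that received grads but were the root itself
        if self._backward is None and self.requires_grad and id(self) in grads:
            g = grads.pop(id(self))
            self.grad = g if self.grad is None else self.grad + g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, splits=splits, axis=axis):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )
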