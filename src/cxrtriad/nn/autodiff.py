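"""Minimal reverse-mode automatic differentiation over numpy arrays.

A ``Tensor`` wraps an ndarray, remembers the op that produced it, and
``backward()`` runs the chain rule over the recorded tape in reverse
topological order. The op set is exactly what the autoencoder and the
windowed transformer need: broadcast arithmetic, matmul, relu/sigmoid,
reductions, reshape/transpose/slicing/gather/concat, and numerically
stable (log-)softmax primitives.

Gradients accumulate into ``.grad`` only for tensors created with
``requires_grad=True`` (parameters) or produced from one. Broadcasting in
forward ops is undone in backward by summing over the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep at many layers
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
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg.copy() if pg.base is not None else pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g
        # non-leaf requires_grad tensors whose grad the caller asked for
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape / dtype sugar ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        a, b = self, self._lift(other)
        return Tensor._node(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other)
        return Tensor._node(
            a.data * b.data,
            (a, b),
            lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._lift(other)
        return Tensor._node(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._node(a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1),))

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._node(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ------------------------------------------

    def relu(self):
        a = self
        return Tensor._node(np.maximum(a.data, 0.0), (a,), lambda g: (g * (a.data > 0),))

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._node(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._node(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._node(out_data, (a,), lambda g: (g * 0.5 / out_data,))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._node(out_data, (a,), lambda g: (g * out_data * (1.0 - out_data),))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops -------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._node(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))

    def __getitem__(self, key):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._node(a.data[key], (a,), backward)

    def take_last(self, indices: np.ndarray):
        """Gather along the last axis with an integer index array.

        For ``x`` of shape ``(..., M)`` and ``indices`` of shape ``S`` the
        result has shape ``(..., *S)``; backward scatter-adds.
        """
        a = self
        indices = np.asarray(indices)
        out_data = np.take(a.data, indices, axis=-1)

        def backward(g):
            lead = int(np.prod(a.shape[:-1], dtype=np.int64)) if a.ndim > 1 else 1
            g2 = g.reshape(lead, -1)
            idx_flat = np.broadcast_to(indices.reshape(1, -1), g2.shape)
            out = np.zeros((lead, a.shape[-1]))
            np.add.at(out, (np.arange(lead)[:, None], idx_flat), g2)
            return (out.reshape(a.shape),)

        return Tensor._node(out_data, (a,), backward)

    # -- softmax family ---------------------------------------------------------

    def softmax(self, axis: int = -1):
        """Numerically stable softmax; tolerates -inf entries (exact zeros)."""
        a = self
        m = np.max(a.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)  # fully masked rows: avoid inf-inf
        e = np.exp(a.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._node(out_data, (a,), backward)

    def log_softmax(self, axis: int = -1):
        a = self
        m = np.max(a.data, axis=axis, keepdims=True)
        shifted = a.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g):
            return (g - soft * g.sum(axis=axis, keepdims=True),)

        return Tensor._node(out_data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)
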