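"""Minimal reverse-mode automatic differentiation over numpy arrays.

All trainable components in this package (the selective state-space blocks,
the convolutional encoder/decoder trunks and the diffusion denoiser) are
expressed as compositions of the primitives defined here.  The engine is a
plain dynamic tape: every operation returns a new :class:`Tensor` holding the
forward value and a closure that scatters the incoming cotangent to the
operation's parents.  Float64 throughout — determinism and numerical headroom
matter more than speed at the problem sizes this package targets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "no_grad"]


class _NoGrad:
    """Context manager that disables graph construction (inference mode)."""

    enabled = False

    def __enter__(self):
        self._prev = _NoGrad.enabled
        _NoGrad.enabled = True
        return self

    def __exit__(self, *exc):
        _NoGrad.enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad.enabled
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        rg = (not _NoGrad.enabled) and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=rg, parents=[p for p in parents if p.requires_grad], backward=backward if rg else None)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- autodiff driver -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (scans)
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._parents:  # free interior grads eagerly
                    node.grad = None

    # -- shape facts ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __pow__(self, p: float):
        a = self
        return Tensor._make(a.data ** p, (a,), lambda g: a._accum(g * p * a.data ** (p - 1)))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
        return Tensor._make(s, (a,), lambda g: a._accum(g * s * (1 - s)))

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
        out_data = a.data * s
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * (s + out_data * (1 - s))))

    def softplus(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
        return Tensor._make(np.logaddexp(0.0, a.data), (a,), lambda g: a._accum(g * s))

    def tanh(self):
        a = self
        t = np.tanh(a.data)
        return Tensor._make(t, (a,), lambda g: a._accum(g * (1 - t * t)))

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = np.where(a.data > 0, 1.0, slope)
        return Tensor._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    # -- structural ops ----------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(a.data.shape)))

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv)))

    def flip(self, axis: int):
        a = self
        return Tensor._make(np.flip(a.data, axis=axis), (a,), lambda g: a._accum(np.flip(g, axis=axis)))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bw)

    def pad_last(self, left: int, right: int):
        """Zero-pad the last axis."""
        a = self
        width = [(0, 0)] * (a.data.ndim - 1) + [(left, right)]
        n = a.data.shape[-1]

        def bw(g):
            a._accum(g[..., left:left + n])

        return Tensor._make(np.pad(a.data, width), (a,), bw)

    def matmul(self, w: "Tensor"):
        """``x @ W`` contracting the last axis of x with the first of W (2-D W)."""
        a, b = self, Tensor._lift(w)

        def bw(g):
            a._accum(g @ b.data.T)
            b._accum(np.tensordot(a.data, g, axes=(tuple(range(a.data.ndim - 1)),) * 2))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    def __matmul__(self, other):
        return self.matmul(other)


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)
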