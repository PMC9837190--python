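"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is a deliberately small engine: just the operations needed by the
LSTM and CNN decoders (dense matmul, elementwise nonlinearities, gate
splitting, 2-D convolution via im2col, max pooling, batch normalisation
and a fused softmax cross-entropy). Gradients are accumulated into
``Tensor.grad`` by :func:`backward`, which walks the graph in reverse
topological order. All arithmetic is float32 unless the caller passes
float64 (the gradient-check tests do).
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "backward"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward_fn
        return out

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            # stored without copying; accumulation below never mutates in
            # place, so sharing the incoming array is safe
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- ops --------------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out_data = a.data @ b.data

        def bwd(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._make(out_data, (a, b), bwd)

    def add(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out_data = a.data + b.data

        def bwd(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), bwd)

    def mul(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out_data = a.data * b.data

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (a, b), bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), bwd)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bwd(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), bwd)

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)
        out_data = self.data[sl]

        def bwd(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bwd)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar tensor, filling ``.grad`` on the graph."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
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

    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward(node.grad)
        # free intermediate grads/graph early; parameters keep their grads
        if node is not loss and node._parents:
            node.grad = None
            node._backward = None
            node._parents = ()
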