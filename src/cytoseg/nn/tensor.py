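"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a numpy array and, when ``requires_grad`` is set
anywhere upstream, records a backward closure on each produced node.
``Tensor.backward()`` topologically sorts the graph and accumulates
gradients into ``.grad`` (a plain numpy array of the same shape/dtype).

Only the operations needed by the segmentation networks live here and in
:mod:`cytoseg.nn.functional`; this is not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None  # closure: receives grad w.r.t. this node
        self._prev: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        """Build an output node; drop the tape if no parent needs grad."""
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def accumulate_grad(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (100+ layer nets)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.accumulate_grad(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/tape once consumed
                node._backward = None
                node._prev = ()

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
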