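"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the topology classifier needs are provided: affine maps,
embedding lookup, elementwise nonlinearities, concatenation/slicing, dropout,
log-softmax and reductions.  Gradients accumulate into ``Tensor.grad`` during
:meth:`Tensor.backward`, which runs a topological sort of the recorded graph.
Everything is float64 by default so finite-difference checks are meaningful.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -----------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    def scale(self, k: float) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * k)

        return Tensor._make(a.data * k, (a,), backward)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self) -> "Tensor":
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return Tensor._make(y, (a,), backward)

    def tanh(self) -> "Tensor":
        a = self
        y = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y))

        return Tensor._make(y, (a,), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        orig = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def __getitem__(self, key) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)

        return Tensor._make(a.data[key], (a,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                            tensors, backward)

    def transpose(self, *axes) -> "Tensor":
        a = self
        axes = axes or tuple(reversed(range(a.data.ndim)))
        inv = tuple(np.argsort(axes))

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(np.full_like(a.data, g))

        return Tensor._make(a.data.sum(), (a,), backward)

    def mean(self) -> "Tensor":
        return self.sum().scale(1.0 / self.data.size)

    # -- composite primitives --------------------------------------------------

    def linear(self, W: "Tensor", b: "Tensor" | None = None) -> "Tensor":
        """Affine map on the last axis: ``x @ W + b`` with W of shape (in, out)."""
        x = self
        y = x.data @ W.data
        if b is not None:
            y = y + b.data

        def backward(g):
            if x.requires_grad:
                x._accum(g @ W.data.T)
            if W.requires_grad:
                W._accum(x.data.reshape(-1, x.data.shape[-1]).T
                         @ g.reshape(-1, g.shape[-1]))
            if b is not None and b.requires_grad:
                b._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))

        parents = (x, W) if b is None else (x, W, b)
        return Tensor._make(y, parents, backward)

    @staticmethod
    def embedding(table: "Tensor", idx: np.ndarray) -> "Tensor":
        """Row lookup ``table[idx]`` with scatter-add gradient into the table."""
        idx = np.asarray(idx)

        def backward(g):
            if table.requires_grad:
                full = np.zeros_like(table.data)
                np.add.at(full, idx.reshape(-1),
                          g.reshape(-1, table.data.shape[1]))
                table._accum(full)

        return Tensor._make(table.data[idx], (table,), backward)

    def log_softmax(self) -> "Tensor":
        """Log-softmax over the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        y = z - logsumexp

        def backward(g):
            if a.requires_grad:
                softmax = np.exp(y)
                a._accum(g - softmax * g.sum(axis=-1, keepdims=True))

        return Tensor._make(y, (a,), backward)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; call only in training mode."""
        a = self
        keep = (rng.random(a.data.shape) >= p) / (1.0 - p)

        def backward(g):
            if a.requires_grad:
                a._accum(g * keep)

        return Tensor._make(a.data * keep, (a,), backward)

    # -- backward pass ---------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Adam:
    """Adam optimizer with the conventional defaults and optional LR decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
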