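"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the package's compute core: a tape of :class:`Tensor` nodes built from
a handful of array primitives (einsum, broadcast add/mul, tanh, reshape,
reductions).  It is deliberately small — just enough to express a feedforward
scalar field together with its spatial gradient and Laplacian trackers, and to
backpropagate any scalar loss assembled from those quantities to the network
parameters.  Everything runs in double precision for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam", "einsum", "affine", "jac_linear", "sum_axis"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape holding a value and its adjoint."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, *, requires_grad=False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # ---- primitives -----------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape) if self.requires_grad else None,
                    _unbroadcast(g, other.shape) if other.requires_grad else None)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.value, self.shape) if self.requires_grad else None,
                _unbroadcast(g * self.value, other.shape) if other.requires_grad else None,
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only by constants")
        return self * (1.0 / other)

    def square(self):
        return self * self

    def tanh(self):
        y = np.tanh(self.value)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def reshape(self, *shape):
        old = self.shape
        out = Tensor(self.value.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(old),)
        return out

    def sum(self):
        out = Tensor(self.value.sum(), parents=(self,))
        out._backward = lambda g: (np.broadcast_to(g, self.shape).copy(),)
        return out

    def mean(self):
        n = self.value.size
        out = Tensor(self.value.mean(), parents=(self,))
        out._backward = lambda g: (np.broadcast_to(g / n, self.shape).copy(),)
        return out

    # ---- autodiff driver ------------------------------------------------

    def backward(self):
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS postorder (deep tapes)
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
        for node in order:
            node.grad = None
        self.grad = np.ones(())
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if not p.requires_grad or g is None:
                    continue
                p.grad = g if p.grad is None else p.grad + g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(value) -> Tensor:
    return Tensor(value)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64, copy=True), requires_grad=True)


def affine(h: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """h @ W.T (+ b) for h (B, i), W (o, i), b (o,)."""
    val = h.value @ W.value.T
    if b is not None:
        val = val + b.value
    parents = (h, W) if b is None else (h, W, b)
    out = Tensor(val, parents=parents)

    def backward(g):
        gh = g @ W.value if h.requires_grad else None
        gW = g.T @ h.value if W.requires_grad else None
        if b is None:
            return (gh, gW)
        return (gh, gW, g.sum(axis=0) if b.requires_grad else None)

    out._backward = backward
    return out


def jac_linear(G: Tensor, W: Tensor) -> Tensor:
    """Propagate a batched Jacobian through a linear layer:
    (B, k, i), (o, i) -> (B, k, o) via G @ W.T.

    Axis layout (batch, input-direction k, units) keeps both the forward
    product and the weight-gradient contraction contiguous GEMMs.
    """
    out = Tensor(np.matmul(G.value, W.value.T), parents=(G, W))

    def backward(g):
        gG = np.matmul(g, W.value) if G.requires_grad else None
        gW = None
        if W.requires_grad:
            o = g.shape[2]
            i = G.value.shape[2]
            gW = np.ascontiguousarray(g).reshape(-1, o).T @ \
                np.ascontiguousarray(G.value).reshape(-1, i)
        return (gG, gW)

    out._backward = backward
    return out


def matmul_right(h: Tensor, W: Tensor) -> Tensor:
    """h @ W for h (B, o), W (o, i)."""
    out = Tensor(h.value @ W.value, parents=(h, W))

    def backward(g):
        return (g @ W.value.T if h.requires_grad else None,
                h.value.T @ g if W.requires_grad else None)

    out._backward = backward
    return out


def sum_axis(t: Tensor, axis: int) -> Tensor:
    shape = t.shape
    out = Tensor(t.value.sum(axis=axis), parents=(t,))

    def backward(g):
        return (np.broadcast_to(np.expand_dims(g, axis), shape).copy(),)

    out._backward = backward
    return out


def einsum(spec: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum.

    All summation indices must appear in at least two of (inputs, output),
    which holds for every contraction used in this package.
    """
    ops = [_as_tensor(t) for t in operands]
    in_specs, out_spec = spec.replace(" ", "").split("->")
    in_specs = in_specs.split(",")
    out = Tensor(np.einsum(spec, *(t.value for t in ops), optimize=True), parents=tuple(ops))

    def backward(g):
        grads = []
        for i, sub in enumerate(in_specs):
            if not ops[i].requires_grad:
                grads.append(None)
                continue
            others = [s for j, s in enumerate(in_specs) if j != i]
            vals = [t.value for j, t in enumerate(ops) if j != i]
            gspec = ",".join([out_spec] + others) + "->" + sub
            grads.append(np.einsum(gspec, g, *vals, optimize=True))
        return tuple(grads)

    out._backward = backward
    return out


# attach as module-level while keeping Tensor importable alone
Tensor.einsum = staticmethod(einsum)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
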