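"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supplies exact gradients of scalar log-densities for the Hamiltonian
sampler in :mod:`mreeg.bayes.nuts`.  Supports the small set of vectorized
operations the model log-posteriors need: broadcasting arithmetic, exp /
log / log1p / tanh / sqrt, gammaln, reductions, matrix products, basic
indexing and gather, and a lower-triangular solve.

Usage: wrap inputs in :class:`Var`, build the scalar output with the
overloaded operators and module functions, then call :func:`backward` on it;
gradients accumulate in ``var.grad``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln as _gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    grad = np.asarray(grad)
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """Node in the computation graph: a numpy value plus vjp closures."""

    __slots__ = ("value", "parents", "grad")
    __array_priority__ = 100  # win against ndarray in mixed expressions

    def __init__(self, value, parents=()):
        self.value = np.asarray(value, dtype=float)
        self.parents = parents  # tuple of (Var, vjp) pairs
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = as_var(other)
        return Var(self.value + o.value,
                   ((self, lambda g: _unbroadcast(g, self.shape)),
                    (o, lambda g: _unbroadcast(g, o.shape))))

    __radd__ = __add__

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __neg__(self):
        return Var(-self.value, ((self, lambda g: -g),))

    def __mul__(self, other):
        o = as_var(other)
        return Var(self.value * o.value,
                   ((self, lambda g: _unbroadcast(g * o.value, self.shape)),
                    (o, lambda g: _unbroadcast(g * self.value, o.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_var(other)
        return Var(self.value / o.value,
                   ((self, lambda g: _unbroadcast(g / o.value, self.shape)),
                    (o, lambda g: _unbroadcast(-g * self.value / o.value**2, o.shape))))

    def __rtruediv__(self, other):
        return as_var(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Var(self.value**e,
                   ((self, lambda g: g * e * self.value**(e - 1)),))

    def __matmul__(self, other):
        o = as_var(other)
        a, b = self.value, o.value
        return Var(a @ b,
                   ((self, lambda g: _matmul_vjp_a(g, a, b)),
                    (o, lambda g: _matmul_vjp_b(g, a, b))))

    def __rmatmul__(self, other):
        return as_var(other) @ self

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return out
        return Var(self.value[idx], ((self, vjp),))

    @property
    def T(self):
        return Var(self.value.T, ((self, lambda g: np.asarray(g).T),))


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def _matmul_vjp_a(g, a, b):
    g = np.asarray(g)
    if b.ndim == 1:
        return np.outer(g, b) if a.ndim == 2 else g * b
    return g @ b.T if a.ndim >= 2 else b @ g


def _matmul_vjp_b(g, a, b):
    g = np.asarray(g)
    if a.ndim == 1:
        return np.outer(a, g) if b.ndim == 2 else g * a
    return a.T @ g


# -- elementwise functions -------------------------------------------------

def exp(x: Var) -> Var:
    x = as_var(x)
    out_val = np.exp(x.value)
    return Var(out_val, ((x, lambda g: g * out_val),))


def log(x: Var) -> Var:
    x = as_var(x)
    return Var(np.log(x.value), ((x, lambda g: g / x.value),))


def log1p(x: Var) -> Var:
    x = as_var(x)
    return Var(np.log1p(x.value), ((x, lambda g: g / (1.0 + x.value)),))


def tanh(x: Var) -> Var:
    x = as_var(x)
    out_val = np.tanh(x.value)
    return Var(out_val, ((x, lambda g: g * (1.0 - out_val**2)),))


def sqrt(x: Var) -> Var:
    x = as_var(x)
    out_val = np.sqrt(x.value)
    return Var(out_val, ((x, lambda g: g * 0.5 / out_val),))


def square(x: Var) -> Var:
    x = as_var(x)
    return Var(x.value**2, ((x, lambda g: g * 2.0 * x.value),))


def gammaln(x: Var) -> Var:
    x = as_var(x)
    return Var(_gammaln(x.value), ((x, lambda g: g * digamma(x.value)),))


def vsum(x: Var, axis=None) -> Var:
    x = as_var(x)
    def vjp(g):
        if axis is None:
            return np.full(x.shape, g)
        return np.broadcast_to(np.expand_dims(g, axis), x.shape).copy()
    return Var(x.value.sum(axis=axis), ((x, vjp),))


def reshape(x: Var, shape: tuple) -> Var:
    x = as_var(x)
    return Var(x.value.reshape(shape),
               ((x, lambda g: np.asarray(g).reshape(x.shape)),))


def gather(x: Var, idx: np.ndarray) -> Var:
    """x[idx] for an integer index array along axis 0 (scatter-add vjp)."""
    return as_var(x)[np.asarray(idx, dtype=int)]


def solve_lower(L: Var, B: Var) -> Var:
    """X = L^-1 B for lower-triangular L (B may be a matrix or vector)."""
    from scipy.linalg import solve_triangular
    L, B = as_var(L), as_var(B)
    X = solve_triangular(L.value, B.value, lower=True)

    def vjp_b(g):
        return solve_triangular(L.value.T, np.asarray(g), lower=False)

    def vjp_l(g):
        gb = solve_triangular(L.value.T, np.asarray(g), lower=False)
        Xv = np.atleast_2d(X) if X.ndim == 1 else X
        gbv = np.atleast_2d(gb) if gb.ndim == 1 else gb
        full = -gbv @ Xv.T if X.ndim > 1 else -np.outer(gb, X)
        return np.tril(full)

    return Var(X, ((B, vjp_b), (L, vjp_l)))


def backward(out: Var) -> None:
    """Accumulate gradients of the scalar ``out`` into every reachable Var."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    for node in topo:
        node.grad = np.zeros_like(node.value)
    out.grad = np.ones_like(out.value)
    for node in reversed(topo):
        for parent, vjp in node.parents:
            parent.grad = parent.grad + vjp(node.grad)
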