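"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed to express the log posterior of the
Gaussian-process functional mixed model: elementwise arithmetic with
broadcasting, a few transcendental functions, matrix products, triangular
solves, Cholesky and symmetric eigendecompositions.  Gradients of the matrix
factorizations follow the standard reverse-mode formulas (Murray 2016 for
Cholesky; the eigh adjoint assumes distinct eigenvalues, which jittered
kernel matrices have generically).

The public surface is the :class:`Var` node type, :func:`constant`, and
:func:`grad`, which evaluates d(scalar output)/d(leaf) for requested leaves.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.lapack import dtrtrs as _dtrtrs


def _solve_tri(L, b, lower=True, trans="N"):
    """Thin wrapper over LAPACK dtrtrs (low call overhead)."""
    x, info = _dtrtrs(L, b, lower=lower, trans=0 if trans == "N" else 1)
    if info != 0:
        raise np.linalg.LinAlgError("singular triangular system")
    return x

__all__ = ["Var", "constant", "grad"]


class Var:
    """A node in the computation tape wrapping an ndarray value."""

    __slots__ = ("value", "parents", "vjps", "grad")

    def __init__(self, value, parents=(), vjps=()):
        self.value = np.asarray(value, dtype=float)
        self.parents = parents
        self.vjps = vjps
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        return Var(self.value + other.value, (self, other),
                   (lambda g: _unbroadcast(g, self.shape),
                    lambda g: _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        other = _wrap(other)
        return Var(self.value - other.value, (self, other),
                   (lambda g: _unbroadcast(g, self.shape),
                    lambda g: _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return _wrap(other).__sub__(self)

    def __mul__(self, other):
        other = _wrap(other)
        return Var(self.value * other.value, (self, other),
                   (lambda g: _unbroadcast(g * other.value, self.shape),
                    lambda g: _unbroadcast(g * self.value, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return Var(self.value / other.value, (self, other),
                   (lambda g: _unbroadcast(g / other.value, self.shape),
                    lambda g: _unbroadcast(-g * self.value / other.value ** 2,
                                           other.shape)))

    def __rtruediv__(self, other):
        return _wrap(other).__truediv__(self)

    def __neg__(self):
        return Var(-self.value, (self,), (lambda g: -g,))

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Var(self.value ** p, (self,),
                   (lambda g: g * p * self.value ** (p - 1),))

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros(self.shape)
            np.add.at(out, idx, g)
            return out
        return Var(self.value[idx], (self,), (vjp,))

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        return Var(self.value.reshape(*shape), (self,),
                   (lambda g: g.reshape(self.shape),))

    @property
    def T(self):
        return Var(self.value.T, (self,), (lambda g: g.T,))

    @property
    def mT(self):
        """Transpose of the last two axes (batched matrix transpose)."""
        return Var(np.swapaxes(self.value, -1, -2), (self,),
                   (lambda g: np.swapaxes(g, -1, -2),))

    def sum(self, axis=None):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            return np.broadcast_to(np.expand_dims(g, axis), self.shape).copy()
        return Var(self.value.sum(axis=axis), (self,), (vjp,))

    def __matmul__(self, other):
        """Matrix product with numpy matmul semantics, including batched
        operands with broadcasting over leading dimensions."""
        other = _wrap(other)
        a, b = self.value, other.value
        swap = lambda x: np.swapaxes(x, -1, -2)

        def vjp_a(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * b
            if a.ndim == 1:          # (k,) @ (..., k, n)
                return _unbroadcast((b @ g[..., :, None])[..., 0], a.shape)
            if b.ndim == 1:          # (..., m, k) @ (k,)
                return _unbroadcast(g[..., :, None] * b, a.shape)
            return _unbroadcast(g @ swap(b), a.shape)

        def vjp_b(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * a
            if a.ndim == 1:
                return _unbroadcast(a[:, None] * g[..., None, :], b.shape)
            if b.ndim == 1:
                return _unbroadcast(
                    (swap(a) @ g[..., :, None])[..., 0], b.shape)
            return _unbroadcast(swap(a) @ g, b.shape)

        return Var(a @ b, (self, other), (vjp_a, vjp_b))


def _wrap(x):
    return x if isinstance(x, Var) else Var(x)


def constant(x):
    """A leaf holding a fixed value (no gradient requested through it)."""
    return Var(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` to ``shape`` by summing broadcast axes."""
    g = np.asarray(g)
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


# -- elementwise functions ------------------------------------------------

def exp(x):
    x = _wrap(x)
    v = np.exp(x.value)
    return Var(v, (x,), (lambda g: g * v,))


def log(x):
    x = _wrap(x)
    return Var(np.log(x.value), (x,), (lambda g: g / x.value,))


def sqrt(x):
    x = _wrap(x)
    v = np.sqrt(x.value)
    return Var(v, (x,), (lambda g: g * 0.5 / v,))


def sin(x):
    x = _wrap(x)
    return Var(np.sin(x.value), (x,), (lambda g: g * np.cos(x.value),))


def tanh(x):
    x = _wrap(x)
    v = np.tanh(x.value)
    return Var(v, (x,), (lambda g: g * (1.0 - v ** 2),))


def square(x):
    x = _wrap(x)
    return Var(x.value ** 2, (x,), (lambda g: g * 2.0 * x.value,))


def minimum2(a, b):
    """Elementwise min of two nodes (subgradient: ties go to the first)."""
    a, b = _wrap(a), _wrap(b)
    take_a = a.value <= b.value
    return Var(np.where(take_a, a.value, b.value), (a, b),
               (lambda g: _unbroadcast(np.where(take_a, g, 0.0), a.shape),
                lambda g: _unbroadcast(np.where(take_a, 0.0, g), b.shape)))


def sigmoid(x):
    return 0.5 * (tanh(_wrap(x) * 0.5) + 1.0)


# -- linear algebra --------------------------------------------------------

def diag_part(x):
    x = _wrap(x)

    def vjp(g):
        out = np.zeros(x.shape)
        np.fill_diagonal(out, g)
        return out

    return Var(np.diag(x.value), (x,), (vjp,))


def _chol_vjp_single(L, Lbar):
    # Murray (2016): Abar = Phi(L^T Lbar) conjugated by L^{-1}
    P = np.tril(L.T @ Lbar)
    P[np.diag_indices_from(P)] *= 0.5
    S = _solve_tri(L, P.T, lower=True, trans="T")
    Abar = _solve_tri(L, S.T, lower=True, trans="T").T
    return 0.5 * (Abar + Abar.T)


def cholesky(a):
    """Lower Cholesky factor; supports a leading batch dimension."""
    a = _wrap(a)
    L = np.linalg.cholesky(a.value)

    def vjp(Lbar):
        if L.ndim == 2:
            return _chol_vjp_single(L, Lbar)
        return np.stack([_chol_vjp_single(L[i], Lbar[i])
                         for i in range(L.shape[0])])

    return Var(L, (a,), (vjp,))


def vmin(x):
    """Minimum of a vector (subgradient assigned to the first argmin)."""
    x = _wrap(x)
    i = int(np.argmin(x.value))

    def vjp(g):
        out = np.zeros(x.shape)
        out[i] = g
        return out

    return Var(x.value.reshape(-1)[i] if x.value.ndim else x.value,
               (x,), (vjp,))


def solve_lower(L, b):
    """x = L^{-1} b for lower-triangular L; b may be a matrix."""
    L, b = _wrap(L), _wrap(b)
    x = _solve_tri(L.value, b.value, lower=True)

    def vjp_L(g):
        bbar = _solve_tri(L.value, g, lower=True, trans="T")
        xm = x if x.ndim == 2 else x[:, None]
        bm = bbar if bbar.ndim == 2 else bbar[:, None]
        return -np.tril(bm @ xm.T)

    def vjp_b(g):
        return _solve_tri(L.value, g, lower=True, trans="T")

    return Var(x, (L, b), (vjp_L, vjp_b))


def eigh(a):
    """Symmetric eigendecomposition; returns (eigenvalues, eigenvectors)."""
    a = _wrap(a)
    lam, Q = np.linalg.eigh(a.value)

    def vjp_lam(g):
        return (Q * g) @ Q.T

    def vjp_Q(g):
        # Pairs with (near-)degenerate eigenvalues are masked: the
        # objectives built here are invariant under rotations within a
        # degenerate eigenspace, for which this is the correct adjoint.
        d = lam[None, :] - lam[:, None]
        tol = 1e-9 * max(np.max(np.abs(lam)), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(np.abs(d) < tol, 0.0, 1.0 / d)
        M = F * (Q.T @ g)
        Abar = Q @ M @ Q.T
        return 0.5 * (Abar + Abar.T)

    return Var(lam, (a,), (vjp_lam,)), Var(Q, (a,), (vjp_Q,))


# -- backward pass ---------------------------------------------------------

def _toposort(node):
    """Iterative post-order topological sort of the tape."""
    order = []
    visited = set()
    stack = [(node, False)]
    while stack:
        n, processed = stack.pop()
        if processed:
            order.append(n)
            continue
        if id(n) in visited:
            continue
        visited.add(id(n))
        stack.append((n, True))
        for p in n.parents:
            if id(p) not in visited:
                stack.append((p, False))
    return order


def grad(output, leaves):
    """Gradient of scalar ``output`` w.r.t. each Var in ``leaves``."""
    if output.value.ndim != 0:
        raise ValueError("grad requires a scalar output")
    order = _toposort(output)
    for n in order:
        n.grad = None
    output.grad = np.ones(())
    for n in reversed(order):
        if n.grad is None:
            continue
        for p, vjp in zip(n.parents, n.vjps):
            contrib = vjp(n.grad)
            if p.grad is None:
                p.grad = np.zeros(p.shape)
            p.grad = p.grad + contrib
    return [leaf.grad if leaf.grad is not None else np.zeros(leaf.shape)
            for leaf in leaves]
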