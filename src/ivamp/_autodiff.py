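"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine exists to make the VAMP-E training objective differentiable
end to end: the loss passes through softmax attention masks, multilayer
perceptrons, time-lagged correlation matrices, symmetric inverse square
roots (whitening) and singular value decompositions. Only the operations
needed for that path are implemented.

Conventions
-----------
* ``Tensor`` wraps a float64/float32 ndarray; ``requires_grad`` marks leaves.
* Gradients are accumulated into ``Tensor.grad`` by ``Tensor.backward()``,
  which must be called on a scalar.
* Matrix-calculus backwards for ``sym_inv_sqrt`` (Daleckii–Krein divided
  differences) and ``svd`` (square case) are validated against central
  finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "elu",
    "exp",
    "kron2",
    "log",
    "matmul",
    "mean",
    "relu",
    "softmax",
    "sqrt",
    "sum_",
    "svd",
    "sym_inv_sqrt",
    "trace_product",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # parents: tuple of (Tensor, vjp) where vjp maps output-grad -> parent-grad
        self._parents = tuple(parents)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def _needs_graph(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape) -> "Tensor":
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        return mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    parents = tuple((p, f) for p, f in parents if p._needs_graph())
    return Tensor(data, parents=parents)


# -- elementwise / structural ops ---------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return _make(
        out,
        [
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ],
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return _make(
        out,
        [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ],
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data
    return _make(
        out,
        [
            (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * a.data / b.data**2, b.data.shape)),
        ],
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data
    return _make(
        out,
        [
            (a, lambda g: g @ b.data.T),
            (b, lambda g: a.data.T @ g),
        ],
    )


def transpose(a: Tensor) -> Tensor:
    return _make(a.data.T, [(a, lambda g: g.T)])


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return _make(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def getitem(a: Tensor, idx) -> Tensor:
    out = a.data[idx]

    def vjp(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return full

    return _make(out, [(a, vjp)])


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for i, t in enumerate(tensors):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        parents.append((t, (lambda s: (lambda g: g[tuple(s)]))(tuple(sl))))
    return _make(out, parents)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2, a.data.shape).copy()

    return _make(out, [(a, vjp)])


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return _make(out, [(a, lambda g: g * out)])


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), [(a, lambda g: g / a.data)])


def sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)
    return _make(out, [(a, lambda g: 0.5 * g / out)])


def abs_(a: Tensor) -> Tensor:
    return _make(np.abs(a.data), [(a, lambda g: g * np.sign(a.data))])


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _make(a.data * mask, [(a, lambda g: g * mask)])


def elu(a: Tensor) -> Tensor:
    pos = a.data > 0
    ex = np.exp(np.minimum(a.data, 0.0))
    out = np.where(pos, a.data, ex - 1.0)
    return _make(out, [(a, lambda g: g * np.where(pos, 1.0, ex))])


def softmax(a: Tensor, axis: int) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return _make(out, [(a, vjp)])


# -- linear-algebra ops -------------------------------------------------------


def kron2(a: Tensor, b: Tensor) -> Tensor:
    """Kronecker product of two 2-D tensors (first factor varies slowest)."""
    m, n = a.data.shape
    p, q = b.data.shape
    out = np.kron(a.data, b.data)

    def vjp_a(g):
        return np.einsum("ipjq,pq->ij", g.reshape(m, p, n, q), b.data)

    def vjp_b(g):
        return np.einsum("ipjq,ij->pq", g.reshape(m, p, n, q), a.data)

    return _make(out, [(a, vjp_a), (b, vjp_b)])


def sym_inv_sqrt(a: Tensor, epsilon: float = 0.0) -> Tensor:
    """(A + eps·I)^(-1/2) for symmetric PSD A, via eigendecomposition.

    Backward uses the Daleckii–Krein formula for spectral matrix functions,
    which stays finite for (near-)degenerate eigenvalues.
    """
    sym = 0.5 * (a.data + a.data.T)
    lam, q = np.linalg.eigh(sym + epsilon * np.eye(sym.shape[0]))
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError(
            "matrix not positive definite after regularization "
            f"(min eigenvalue {lam.min():.3e}); increase epsilon"
        )
    f = lam**-0.5
    out = (q * f) @ q.T

    def vjp(g):
        gq = q.T @ (0.5 * (g + g.T)) @ q
        dl = lam[:, None] - lam[None, :]
        # divided differences of f(x) = x^(-1/2); derivative on the diagonal
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (f[:, None] - f[None, :]) / dl
        fill = -0.5 * lam**-1.5
        p[np.abs(dl) < 1e-12 * max(1.0, np.abs(lam).max())] = 0.0
        p[np.diag_indices_from(p)] = fill
        # degenerate off-diagonal pairs also take the derivative value
        mask = (np.abs(dl) < 1e-12 * max(1.0, np.abs(lam).max())) & ~np.eye(
            len(lam), dtype=bool
        )
        if mask.any():
            p[mask] = np.broadcast_to(fill[:, None], p.shape)[mask]
        return q @ (p * gq) @ q.T

    return _make(out, [(a, vjp)])


def svd(a: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """SVD of a square matrix: returns (U, s, V) with A = U diag(s) Vᵀ.

    The backward pass assumes non-degenerate singular values (generic for
    sampled correlation matrices); near-degenerate gaps are clamped.
    """
    u, s, vt = np.linalg.svd(a.data)
    v = vt.T
    n = a.data.shape[0]

    s2 = s**2
    diff = s2[None, :] - s2[:, None]
    eye = np.eye(n, dtype=bool)
    # clamp tiny gaps to keep F finite; exact degeneracy gives 0 contribution
    safe = np.where(np.abs(diff) < 1e-12, np.inf, diff)
    F = np.where(eye, 0.0, 1.0 / safe)

    def vjp_u(g):
        ug = u.T @ g
        return u @ ((F * (ug - ug.T)) @ np.diag(s)) @ v.T

    def vjp_s(g):
        return u @ np.diag(g) @ v.T

    def vjp_v(g):
        vg = v.T @ g
        return u @ (np.diag(s) @ (F * (vg - vg.T))) @ v.T

    ut = _make(u, [(a, vjp_u)])
    st = _make(s, [(a, vjp_s)])
    vt_ = _make(v, [(a, vjp_v)])
    return ut, st, vt_


def trace_product(a: Tensor, b: Tensor) -> Tensor:
    """tr(A @ B) without forming the product."""
    return sum_(mul(a, transpose(b)))
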