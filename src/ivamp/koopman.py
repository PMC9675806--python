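"""Koopman-model estimation for a single (sub)system.

Given fuzzy state assignments χ(x_t) ∈ R^n (non-negative rows summing to
one, e.g. SoftMax outputs), this module estimates time-lagged correlation
matrices, the whitened half-weighted matrix K̄ = C00^(-1/2) C0τ Cττ^(-1/2)
and its singular value decomposition, the VAMP-E score, the Koopman matrix
T = C00^(-1) C0τ, and its spectral quantities (eigenfunctions and implied
timescales t_i = -τ / log|λ_i|).

All functions take and return plain numpy arrays; nothing here is part of
the differentiable training path (see :mod:`ivamp.model` for that).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "CorrelationSet",
    "KoopmanModel",
    "SpectralModel",
    "estimate_correlations",
    "inverse_sqrt",
    "whitened_svd",
    "vamp_e_score",
    "koopman_matrix",
    "spectral_analysis",
]

#: relative Tikhonov regularization added to C00/Cττ before inversion
DEFAULT_EPSILON = 1e-6
#: |λ| above this is treated as a stationary process (infinite timescale)
STATIONARY_THRESHOLD = 1.0 - 1e-9
#: default bound on |Im λ| / |λ| for the spectral decomposition to be valid
DEFAULT_IMAG_TOL = 1e-3


@dataclasses.dataclass(frozen=True)
class CorrelationSet:
    """Empirical time-lagged correlation matrices of one (sub)system.

    C00 = (1/L) Σ_t χ(x_t) χ(x_t)ᵀ, C0τ = (1/L) Σ_t χ(x_t) χ(x_{t+τ})ᵀ,
    Cττ = (1/L) Σ_t χ(x_{t+τ}) χ(x_{t+τ})ᵀ over the L collected pairs.
    """

    c00: np.ndarray
    c0t: np.ndarray
    ctt: np.ndarray
    n_pairs: int
    lag: float

    @property
    def n_states(self) -> int:
        return self.c00.shape[0]

    def __post_init__(self):
        for name in ("c00", "c0t", "ctt"):
            m = getattr(self, name)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square, got shape {m.shape}")
        if not (self.c00.shape == self.c0t.shape == self.ctt.shape):
            raise ValueError("correlation matrices must share one shape")


@dataclasses.dataclass(frozen=True)
class KoopmanModel:
    """Whitened SVD factors of one subsystem.

    ``u`` and ``v`` map state assignments onto the left/right singular
    functions, f(x_t) = uᵀ χ(x_t) and g(x_{t+τ}) = vᵀ χ(x_{t+τ}); ``k`` is
    the diagonal matrix of singular values, sorted non-increasing.
    """

    u: np.ndarray
    v: np.ndarray
    k: np.ndarray
    whitening_left: np.ndarray
    whitening_right: np.ndarray

    @property
    def singular_values(self) -> np.ndarray:
        return np.diag(self.k)

    @property
    def n_states(self) -> int:
        return self.u.shape[0]


@dataclasses.dataclass(frozen=True)
class SpectralModel:
    """Eigendecomposition T = Q Λ Q^(-1) of a Koopman/transition matrix."""

    transition: np.ndarray
    eigenvalues: np.ndarray
    eigenvector_matrix: np.ndarray
    timescales: np.ndarray
    lag: float

    def eigenfunction_map(self, chi: np.ndarray) -> np.ndarray:
        """Project state assignments onto eigenfunctions, φ(x) = Qᵀ χ(x)."""
        return chi @ self.eigenvector_matrix


def estimate_correlations(
    chi_t: np.ndarray, chi_tau: np.ndarray, lag: float = 1.0
) -> CorrelationSet:
    """Empirical C00, C0τ, Cττ from L paired state assignments.

    Parameters
    ----------
    chi_t, chi_tau
        Arrays of shape (L, n) holding χ(x_t) and χ(x_{t+τ}) per pair.
    lag
        Lag time τ carried as metadata (trajectory-step or physical units).
    """
    chi_t = np.atleast_2d(np.asarray(chi_t, dtype=np.float64))
    chi_tau = np.atleast_2d(np.asarray(chi_tau, dtype=np.float64))
    if chi_t.shape != chi_tau.shape:
        raise ValueError(
            f"paired assignments differ in shape: {chi_t.shape} vs {chi_tau.shape}"
        )
    L = chi_t.shape[0]
    if L == 0:
        raise ValueError("no time-lagged pairs supplied")
    return CorrelationSet(
        c00=chi_t.T @ chi_t / L,
        c0t=chi_t.T @ chi_tau / L,
        ctt=chi_tau.T @ chi_tau / L,
        n_pairs=L,
        lag=lag,
    )


def inverse_sqrt(m: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """(M + ε·I)^(-1/2) of a symmetric PSD matrix via eigendecomposition."""
    m = np.asarray(m, dtype=np.float64)
    if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
        raise ValueError("matrix is not symmetric")
    lam, q = np.linalg.eigh(0.5 * (m + m.T))
    lam = lam + epsilon
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError(
            f"matrix not positive definite after regularization "
            f"(min eigenvalue {lam.min():.3e})"
        )
    return (q * lam**-0.5) @ q.T


def _regularizer(c: np.ndarray, epsilon: float) -> float:
    # scale-aware Tikhonov term: epsilon × mean diagonal
    return epsilon * np.trace(c) / c.shape[0]


def whitened_svd(corr: CorrelationSet, epsilon: float = DEFAULT_EPSILON) -> KoopmanModel:
    """Singular functions/values from K̄ = C00^(-1/2) C0τ Cττ^(-1/2).

    The whitened matrix is decomposed as K̄ = A K Bᵀ; the returned maps are
    u = C00^(-1/2) A and v = Cττ^(-1/2) B. When K̄ is symmetric within
    tolerance the decomposition is computed from the symmetric
    eigendecomposition (stable sorted by |λ|), otherwise by full SVD.
    """
    w_left = inverse_sqrt(corr.c00, _regularizer(corr.c00, epsilon))
    w_right = inverse_sqrt(corr.ctt, _regularizer(corr.ctt, epsilon))
    kbar = w_left @ corr.c0t @ w_right
    if np.allclose(kbar, kbar.T, atol=1e-10 * max(1.0, np.abs(kbar).max())):
        lam, q = np.linalg.eigh(0.5 * (kbar + kbar.T))
        order = np.argsort(-np.abs(lam), kind="stable")
        lam, q = lam[order], q[:, order]
        a = q
        b = q * np.sign(lam)[None, :]  # absorb signs so singular values ≥ 0
        s = np.abs(lam)
    else:
        a, s, bt = np.linalg.svd(kbar)
        b = bt.T
    return KoopmanModel(
        u=w_left @ a,
        v=w_right @ b,
        k=np.diag(s),
        whitening_left=w_left,
        whitening_right=w_right,
    )


def vamp_e_score(model: KoopmanModel, corr: CorrelationSet) -> float:
    """VAMP-E score tr[2K Uᵀ C0τ V − K Uᵀ C00 U K Vᵀ Cττ V].

    Evaluated at the whitened-SVD optimum of the same correlations this
    equals the sum of squared singular values; with mismatched model and
    data it measures how well the model predicts the data's dynamics.
    """
    u, v, k = model.u, model.v, model.k
    if u.shape[0] != corr.n_states:
        raise ValueError(
            f"model has {u.shape[0]} states but correlations have {corr.n_states}"
        )
    first = 2.0 * k @ u.T @ corr.c0t @ v
    second = k @ u.T @ corr.c00 @ u @ k @ v.T @ corr.ctt @ v
    return float(np.trace(first - second))


def koopman_matrix(corr: CorrelationSet, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Koopman matrix T = (C00 + εI)^(-1) C0τ."""
    reg = _regularizer(corr.c00, epsilon)
    c00 = corr.c00 + reg * np.eye(corr.n_states)
    try:
        return np.linalg.solve(c00, corr.c0t)
    except np.linalg.LinAlgError as err:  # pragma: no cover - extreme inputs
        raise np.linalg.LinAlgError(
            "C00 singular beyond regularization; increase epsilon"
        ) from err


def spectral_analysis(
    transition: np.ndarray,
    lag: float = 1.0,
    imag_tol: float = DEFAULT_IMAG_TOL,
) -> SpectralModel:
    """Eigendecomposition and implied timescales of a Koopman matrix.

    Timescales are t_i = −τ / log|λ_i|, with eigenvalues sorted by modulus
    descending. Stationary eigenvalues (|λ| ≈ 1) get an infinite timescale.
    Eigenvalues with relative imaginary part above ``imag_tol`` indicate the
    spectrum is not approximately real-valued and raise an error.
    """
    transition = np.asarray(transition, dtype=np.float64)
    if transition.ndim != 2 or transition.shape[0] != transition.shape[1]:
        raise ValueError("transition matrix must be square")
    lam, q = np.linalg.eig(transition)
    order = np.argsort(-np.abs(lam), kind="stable")
    lam, q = lam[order], q[:, order]
    rel_imag = np.abs(lam.imag) / np.maximum(np.abs(lam), 1e-300)
    if np.any(rel_imag > imag_tol):
        raise ValueError(
            "eigendecomposition is not approximately real-valued "
            f"(max |Im λ|/|λ| = {rel_imag.max():.3e} > {imag_tol:g}); "
            "implied timescales are undefined"
        )
    lam_real = lam.real
    mod = np.abs(lam_real)
    # singular-value-like clipping applies to timescale reporting only
    mod_clipped = np.minimum(mod, 1.0)
    timescales = np.empty_like(mod)
    stationary = mod >= STATIONARY_THRESHOLD
    with np.errstate(divide="ignore"):
        timescales[~stationary] = -lag / np.log(mod_clipped[~stationary])
    timescales[stationary] = np.inf
    return SpectralModel(
        transition=transition,
        eigenvalues=lam_real,
        eigenvector_matrix=q.real,
        timescales=timescales,
        lag=lag,
    )
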