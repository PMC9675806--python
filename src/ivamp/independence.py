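"""Kronecker construction of global models and independence metrics.

If a system decomposes into independent Markovian subsystems, the global
state assignment is the Kronecker product of the subsystem assignments and
the global Koopman model factorizes: its singular values/functions are the
Kronecker products of the subsystem ones, and the global VAMP-E score is
the product of subsystem scores. Deviations from those identities are the
independence metrics M_U, M_V, M_UV (orthonormality / correlation of the
constructed singular functions) and M_R (score-product ratio), the last of
which is also the pairwise training penalty.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from functools import reduce

import numpy as np

from .koopman import CorrelationSet, KoopmanModel, estimate_correlations, vamp_e_score

__all__ = [
    "GlobalConstruction",
    "IndependenceReport",
    "TrainingConfig",
    "kron_state_product",
    "construct_global_model",
    "global_correlations",
    "global_vamp_e",
    "independence_scores",
    "pairwise_loss",
]

#: largest global dimension for which the full N-way construction is formed
MAX_GLOBAL_DIM = 4096


@dataclasses.dataclass(frozen=True)
class GlobalConstruction:
    """Candidate global Koopman model built from subsystem models.

    K^G = ⊗_i K^i (diagonal), U^G = ⊗_i U^i, V^G = ⊗_i V^i, with the first
    subsystem varying slowest (standard Kronecker convention).
    """

    k_global: np.ndarray
    u_global: np.ndarray
    v_global: np.ndarray
    subsystem_dims: tuple[int, ...]

    @property
    def dim(self) -> int:
        return int(np.prod(self.subsystem_dims))


@dataclasses.dataclass(frozen=True)
class IndependenceReport:
    """The four independence metrics; all are ≥ 0 and vanish exactly for
    analytically independent subsystems."""

    m_u: float
    m_v: float
    m_uv: float
    m_r: float
    per_pair: dict[str, float] | None = None
    variant: str = "full"

    def to_json(self) -> str:
        return json.dumps(
            {
                "m_u": self.m_u,
                "m_v": self.m_v,
                "m_uv": self.m_uv,
                "m_r": self.m_r,
                "per_pair": self.per_pair,
            },
            indent=2,
        )


@dataclasses.dataclass
class TrainingConfig:
    """Hyperparameters of an iVAMPnet fit.

    ``xi`` weighs the pairwise independence penalty against the VAMP-E
    score; it must be large enough to decouple the subsystems but small
    enough not to suppress their kinetics. A linear warm-up over the first
    ``xi_warmup`` fraction of epochs lets kinetics form before decoupling
    pressure sets in.
    """

    n_subsystems: int = 2
    states_per_subsystem: tuple[int, ...] = (2, 3)
    lag: int = 1
    xi: float = 1.0
    xi_warmup: float = 0.1
    theta: float = 0.02
    sigma: float | None = None  # None → 0.15 × mean per-feature std of the data
    lr: float = 1e-3
    mask_lr: float = 0.05
    batch: int = 4096
    epochs: int = 30
    hidden: tuple[int, ...] = (100, 100)
    seed: int = 0
    validation_fraction: float = 0.1
    epsilon: float = 1e-6
    standardize: bool = True
    restarts: int = 1
    probe_epochs: int = 4
    mask_freeze_epochs: int = 0
    mask_anneal_epochs: int = 0

    def __post_init__(self):
        if self.xi < 0:
            raise ValueError("xi must be non-negative")
        if self.n_subsystems < 1:
            raise ValueError("need at least one subsystem")
        if len(self.states_per_subsystem) != self.n_subsystems:
            raise ValueError("states_per_subsystem length must equal n_subsystems")


def kron_state_product(assignments: list[np.ndarray]) -> np.ndarray:
    """Global state vector ⊗_i χ^i; first subsystem varies slowest.

    Accepts single vectors (n_i,) or batches (L, n_i); batches are combined
    row-wise.
    """
    if len(assignments) == 0:
        raise ValueError("no subsystem assignments given")
    arrays = [np.asarray(a, dtype=np.float64) for a in assignments]
    if arrays[0].ndim == 1:
        return reduce(np.kron, arrays)
    out = arrays[0]
    for a in arrays[1:]:
        out = (out[:, :, None] * a[:, None, :]).reshape(out.shape[0], -1)
    return out


def construct_global_model(models: list[KoopmanModel]) -> GlobalConstruction:
    """Kronecker products of the subsystem singular value/function maps."""
    if len(models) == 0:
        raise ValueError("no subsystem models given")
    k = reduce(np.kron, [m.k for m in models])
    u = reduce(np.kron, [m.u for m in models])
    v = reduce(np.kron, [m.v for m in models])
    return GlobalConstruction(
        k_global=k,
        u_global=u,
        v_global=v,
        subsystem_dims=tuple(m.n_states for m in models),
    )


def global_correlations(
    assignments_t: list[np.ndarray],
    assignments_tau: list[np.ndarray],
    lag: float = 1.0,
    chunk: int = 8192,
) -> CorrelationSet:
    """Correlation matrices of the Kronecker-product global assignments.

    Accumulated in chunks so long trajectories never materialize the full
    L × ∏n_i product matrix.
    """
    L = assignments_t[0].shape[0]
    dim = int(np.prod([a.shape[1] for a in assignments_t]))
    c00 = np.zeros((dim, dim))
    c0t = np.zeros((dim, dim))
    ctt = np.zeros((dim, dim))
    for start in range(0, L, chunk):
        sl = slice(start, min(start + chunk, L))
        gt = kron_state_product([a[sl] for a in assignments_t])
        gtau = kron_state_product([a[sl] for a in assignments_tau])
        c00 += gt.T @ gt
        c0t += gt.T @ gtau
        ctt += gtau.T @ gtau
    return CorrelationSet(c00=c00 / L, c0t=c0t / L, ctt=ctt / L, n_pairs=L, lag=lag)


def global_vamp_e(construction: GlobalConstruction, global_corr: CorrelationSet) -> float:
    """Global VAMP-E score of the constructed model against global data.

    For exactly independent subsystems this equals the product of the
    subsystem VAMP-E scores (necessary condition for independence).
    """
    if construction.dim != global_corr.n_states:
        raise ValueError(
            f"construction dimension {construction.dim} does not match "
            f"correlations ({global_corr.n_states})"
        )
    model = KoopmanModel(
        u=construction.u_global,
        v=construction.v_global,
        k=construction.k_global,
        whitening_left=np.empty(0),
        whitening_right=np.empty(0),
    )
    return vamp_e_score(model, global_corr)


def _mean_abs(m: np.ndarray) -> float:
    return float(np.mean(np.abs(m)))


def independence_scores(
    construction: GlobalConstruction,
    global_corr: CorrelationSet,
    subsystem_scores: list[float],
    per_pair: dict[str, float] | None = None,
    variant: str = "full",
) -> IndependenceReport:
    """M_U, M_V, M_UV from the orthonormality/correlation identities and
    M_R from the score-product ratio; the norms are simple means of the
    absolute deviations."""
    u, v, k = construction.u_global, construction.v_global, construction.k_global
    if construction.dim != global_corr.n_states:
        raise ValueError("construction and correlations disagree in dimension")
    eye = np.eye(construction.dim)
    m_u = _mean_abs(u.T @ global_corr.c00 @ u - eye)
    m_v = _mean_abs(v.T @ global_corr.ctt @ v - eye)
    m_uv = _mean_abs(u.T @ global_corr.c0t @ v - k)
    r_global = global_vamp_e(construction, global_corr)
    m_r = abs(r_global - float(np.prod(subsystem_scores))) / r_global
    return IndependenceReport(
        m_u=m_u, m_v=m_v, m_uv=m_uv, m_r=m_r, per_pair=per_pair, variant=variant
    )


def pairwise_independence_scores(
    models: list[KoopmanModel],
    assignments_t: list[np.ndarray],
    assignments_tau: list[np.ndarray],
    subsystem_scores: list[float],
    lag: float = 1.0,
) -> IndependenceReport:
    """Independence metrics as maxima over all subsystem pairs.

    Used when the full N-way construction would exceed ``MAX_GLOBAL_DIM``;
    the per-pair M_R values are reported alongside.
    """
    n = len(models)
    m_u = m_v = m_uv = m_r = 0.0
    pair_r: dict[str, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        constr = construct_global_model([models[i], models[j]])
        corr = global_correlations(
            [assignments_t[i], assignments_t[j]],
            [assignments_tau[i], assignments_tau[j]],
            lag=lag,
        )
        rep = independence_scores(
            constr, corr, [subsystem_scores[i], subsystem_scores[j]]
        )
        pair_r[f"{i}-{j}"] = rep.m_r
        m_u, m_v = max(m_u, rep.m_u), max(m_v, rep.m_v)
        m_uv, m_r = max(m_uv, rep.m_uv), max(m_r, rep.m_r)
    return IndependenceReport(
        m_u=m_u, m_v=m_v, m_uv=m_uv, m_r=m_r, per_pair=pair_r, variant="max-over-pairs"
    )


def pairwise_loss(
    models: list[KoopmanModel],
    pairwise_corr: dict[tuple[int, int], CorrelationSet],
    subsystem_scores: list[float],
    xi: float,
) -> float:
    """Training loss L = −Σ_{i<j} R_E^{ij} + ξ Σ_{i<j} |R_E^{ij} − R_E^i R_E^j| / R_E^{ij}.

    The pairwise global scores R_E^{ij} come from the Kronecker pair
    construction, avoiding the full global state space. A single subsystem
    yields the degenerate loss −R_E^1.
    """
    n = len(models)
    if n == 1:
        return -subsystem_scores[0]
    loss = 0.0
    for i, j in itertools.combinations(range(n), 2):
        if (i, j) not in pairwise_corr:
            raise KeyError(f"missing correlation set for pair ({i}, {j})")
        constr = construct_global_model([models[i], models[j]])
        r_ij = global_vamp_e(constr, pairwise_corr[(i, j)])
        if r_ij <= 0:
            raise ValueError(f"degenerate pairwise score R_E^({i},{j}) = {r_ij:.3e}")
        loss += -r_ij + xi * abs(r_ij - subsystem_scores[i] * subsystem_scores[j]) / r_ij
    return loss
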