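"""Trainable attention masks that route input features to subsystems.

The mask G ∈ [0,1]^{D×N} is derived from raw trainable weights in four
steps: a softmax over the feature axis per subsystem (so a subsystem
cannot attend to everything), clipping below a threshold θ (sparsity),
appending a constant dummy column c (absorbing features no subsystem
needs), and per-feature normalization across subsystems plus dummy.
Masked inputs are interpolated with Gaussian noise so downstream networks
cannot undo the attention weighting.

For proteins the mask lives on residues and is smoothed by overlapping
windows along the chain; residue-pair distance features are then scaled
as x_ij = G_i G_j exp(−d_ij).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "MaskSpec",
    "ResidueMaskSpec",
    "build_mask",
    "apply_mask",
    "residue_window_weights",
    "scale_distance_features",
    "window_coverage_matrix",
    "write_residue_weights",
]


@dataclasses.dataclass
class MaskSpec:
    """Raw attention weights g (D features × N subsystems) with the
    threshold θ, dummy constant c and noise scale σ."""

    raw_weights: np.ndarray
    theta: float = 0.02
    dummy_const: float | None = None  # None → 1/D
    noise_scale: float = 0.0

    def __post_init__(self):
        self.raw_weights = np.asarray(self.raw_weights, dtype=np.float64)
        if self.raw_weights.ndim != 2:
            raise ValueError("raw_weights must be D × N")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.dummy_const is None:
            self.dummy_const = 1.0 / self.raw_weights.shape[0]
        if self.dummy_const <= 0:
            raise ValueError("dummy constant must be positive")


@dataclasses.dataclass
class ResidueMaskSpec:
    """Windowed residue-level attention weights for protein chains.

    ``window_weights`` has one row per window (W × N); window w covers
    residues [w·step, w·step + window_size). A residue's pre-clipping
    weight is the product of the softmax-normalized weights of all windows
    covering it, which smooths attention along the chain.
    """

    window_weights: np.ndarray
    window_size: int = 4
    step: int = 2
    n_residues: int = 0
    theta: float = 0.02
    dummy_const: float | None = None

    def __post_init__(self):
        self.window_weights = np.asarray(self.window_weights, dtype=np.float64)
        if self.window_weights.ndim != 2:
            raise ValueError("window_weights must be W × N")
        w = self.window_weights.shape[0]
        covered = np.zeros(self.n_residues, dtype=bool)
        for i in range(w):
            covered[i * self.step : i * self.step + self.window_size] = True
        if self.n_residues and not covered.all():
            missing = int(np.flatnonzero(~covered)[0])
            raise ValueError(
                f"window layout leaves residue {missing} uncovered "
                f"(W={w}, size={self.window_size}, step={self.step})"
            )
        if self.dummy_const is None:
            self.dummy_const = 1.0 / max(self.n_residues, 1)


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _mask_pipeline(g1: np.ndarray, theta: float, c: float) -> np.ndarray:
    """Clip, append dummy, normalize per feature, drop dummy."""
    g2 = np.maximum(g1 - theta, 0.0)
    g3 = np.concatenate([g2, np.full((g1.shape[0], 1), c)], axis=1)
    g4 = g3 / g3.sum(axis=1, keepdims=True)
    return g4[:, :-1]


def build_mask(spec: MaskSpec) -> np.ndarray:
    """Mask G ∈ [0,1]^{D×N} from raw weights.

    g1 = softmax over features per subsystem, g2 = max(g1 − θ, 0),
    g3 = [g2, c], g4 = g3 / row-sum, G = g4 without the dummy column.
    """
    g1 = _softmax(spec.raw_weights, axis=0)
    return _mask_pipeline(g1, spec.theta, spec.dummy_const)


def apply_mask(
    G: np.ndarray,
    x: np.ndarray,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Masked, noise-interpolated inputs Y of shape (B, D, N).

    Y[:, :, j] = G[:, j] ⊙ x + ε with ε ~ N(0, σ(1 − G)) drawn
    independently per entry; G = 1 passes the feature through unchanged,
    G = 0 replaces it with pure noise. σ(1 − G) is the noise standard
    deviation, so the attention weight linearly interpolates between
    feature and noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    G = np.asarray(G, dtype=np.float64)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != G.shape[0]:
        raise ValueError(f"feature dimension mismatch: x has {x.shape[1]}, mask {G.shape[0]}")
    y = x[:, :, None] * G[None, :, :]
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(size=y.shape) * (sigma * (1.0 - G))[None, :, :]
    return y


def window_coverage_matrix(n_residues: int, n_windows: int, window_size: int, step: int) -> np.ndarray:
    """Binary matrix C (R × W) with C[r, w] = 1 iff window w covers residue r.

    The per-residue product of covering-window weights is then
    exp(C @ log ḡ), which keeps the construction a plain matrix product.
    """
    c = np.zeros((n_residues, n_windows))
    for w in range(n_windows):
        c[w * step : w * step + window_size, w] = 1.0
    return c


def write_residue_weights(path, residue_mask: np.ndarray, subsystem: int) -> None:
    """Write per-residue weights of one subsystem as two-column plain text
    (residue index, weight) for structure coloring."""
    w = np.asarray(residue_mask)[:, subsystem]
    with open(path, "w") as fh:
        for i, val in enumerate(w):
            fh.write(f"{i} {val:.6f}\n")


def residue_window_weights(spec: ResidueMaskSpec) -> np.ndarray:
    """Per-residue mask (R × N) from windowed weights.

    ḡ = softmax over windows; each residue's pre-clipping weight is the
    product of its covering windows' ḡ; the clipping/dummy/normalization
    steps then proceed exactly as in :func:`build_mask`.
    """
    gbar = _softmax(spec.window_weights, axis=0)
    W, N = gbar.shape
    R = spec.n_residues
    g1 = np.ones((R, N))
    for w in range(W):
        lo, hi = w * spec.step, min(w * spec.step + spec.window_size, R)
        g1[lo:hi] *= gbar[w]
    return _mask_pipeline(g1, spec.theta, spec.dummy_const)


def scale_distance_features(
    residue_mask: np.ndarray, distances: np.ndarray, subsystem: int
) -> np.ndarray:
    """Distance features scaled by attention: x_ij = G_i G_j exp(−d_ij).

    The diagonal (i = j) is excluded (set to zero).
    """
    d = np.asarray(distances, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    g = np.asarray(residue_mask, dtype=np.float64)[:, subsystem]
    x = g[:, None] * g[None, :] * np.exp(-d)
    np.fill_diagonal(x, 0.0)
    return x
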