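"""Synthetic benchmark generators: independent hidden Markov chains with
Gaussian emissions.

Two standard systems are provided:

* a two-subsystem benchmark — one 2-state and one 3-state chain emitting
  independently onto the x and y axis of a 2-D feature space (6 global
  states);
* a hypercube benchmark — ten independent 2-state chains with distinct
  timescales, emitted pairwise into rotated 2-D planes, plus ten pure
  Gaussian noise dimensions (1024 global states embedded in 20 dimensions).

Defaults are chosen so the subsystem eigenvalues are 0.90 for the 2-state
chain and (0.89, 0.66) for the 3-state chain, with emission modes well
separated relative to the emission width.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

__all__ = [
    "BenchmarkSpec",
    "GroundTruth",
    "two_state_matrix",
    "three_state_matrix",
    "sample_markov_chain",
    "gaussian_emission",
    "make_two_subsystem_benchmark",
    "make_hypercube_benchmark",
    "make_cooperative_control",
]


def two_state_matrix(self_probability: float = 0.95) -> np.ndarray:
    """Symmetric 2-state chain; second eigenvalue λ₂ = 2p − 1."""
    p = self_probability
    return np.array([[p, 1.0 - p], [1.0 - p, p]])


def three_state_matrix(lam2: float = 0.89, lam3: float = 0.66) -> np.ndarray:
    """3-state chain with uniform stationary distribution and eigenvalues
    (1, lam2, lam3), synthesized spectrally.

    The non-stationary eigenvectors are rotated within their plane (by
    5π/6 for the defaults) so that all entries are non-negative.
    """
    u = np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0)
    v = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)
    phi = 5.0 * np.pi / 6.0
    q2 = np.cos(phi) * u + np.sin(phi) * v
    q3 = -np.sin(phi) * u + np.cos(phi) * v
    t = np.ones((3, 3)) / 3.0 + lam2 * np.outer(q2, q2) + lam3 * np.outer(q3, q3)
    if t.min() < 0:
        raise ValueError(f"eigenvalues ({lam2}, {lam3}) give negative entries")
    return t


@dataclasses.dataclass
class BenchmarkSpec:
    """Ground-truth parameters of a hidden-Markov benchmark."""

    transition_matrices: list[np.ndarray]
    emission_means: list[np.ndarray]
    emission_width: float = 0.2
    rotation_angle: float = np.pi / 4.0
    n_noise_dims: int = 0
    noise_width: float = 1.0
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        self.transition_matrices = [
            np.asarray(t, dtype=np.float64) for t in self.transition_matrices
        ]
        self.emission_means = [np.asarray(m, dtype=np.float64) for m in self.emission_means]
        for t, m in zip(self.transition_matrices, self.emission_means):
            _check_stochastic(t)
            if t.shape[0] != m.shape[0]:
                raise ValueError("one emission mean required per hidden state")

    @classmethod
    def two_subsystem(cls, n_steps: int = 100_000, seed: int = 0) -> "BenchmarkSpec":
        return cls(
            transition_matrices=[two_state_matrix(), three_state_matrix()],
            emission_means=[np.array([-1.0, 1.0]), np.array([-1.0, 0.0, 1.0])],
            n_steps=n_steps,
            seed=seed,
        )

    @classmethod
    def hypercube(
        cls, n_chains: int = 10, n_noise_dims: int = 10,
        n_steps: int = 100_000, seed: int = 0,
    ) -> "BenchmarkSpec":
        # self-probabilities spaced in [0.90, 0.99] → unique timescales
        probs = np.linspace(0.90, 0.99, n_chains)
        return cls(
            transition_matrices=[two_state_matrix(p) for p in probs],
            emission_means=[np.array([-1.0, 1.0])] * n_chains,
            n_noise_dims=n_noise_dims,
            n_steps=n_steps,
            seed=seed,
        )


@dataclasses.dataclass
class GroundTruth:
    """What generated a benchmark trajectory, for parameter-recovery checks."""

    spec: BenchmarkSpec
    hidden_states: list[np.ndarray]

    @property
    def eigenvalues(self) -> list[np.ndarray]:
        out = []
        for t in self.spec.transition_matrices:
            lam = np.sort(np.abs(np.linalg.eigvals(t)))[::-1]
            out.append(lam)
        return out

    @property
    def timescales(self) -> list[np.ndarray]:
        return [-1.0 / np.log(lam[1:]) for lam in self.eigenvalues]

    def to_json(self) -> str:
        s = self.spec
        return json.dumps(
            {
                "transition_matrices": [t.tolist() for t in s.transition_matrices],
                "emission_means": [m.tolist() for m in s.emission_means],
                "emission_width": s.emission_width,
                "rotation_angle": s.rotation_angle,
                "n_noise_dims": s.n_noise_dims,
                "noise_width": s.noise_width,
                "n_steps": s.n_steps,
                "seed": s.seed,
            },
            indent=2,
        )


def _check_stochastic(t: np.ndarray) -> None:
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")


def sample_markov_chain(
    T: np.ndarray, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Discrete trajectory of length ``n_steps``; initial state uniform."""
    T = np.asarray(T, dtype=np.float64)
    _check_stochastic(T)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.integers(n)
    draws = rng.random(n_steps - 1) if n_steps > 1 else np.empty(0)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], draws[t - 1], side="right")
    return states


def gaussian_emission(
    states: np.ndarray,
    means: np.ndarray,
    sigma_tilde: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous 1-D observable: value_t ~ N(μ_state_t, σ̃)."""
    states = np.asarray(states)
    means = np.asarray(means, dtype=np.float64)
    if states.max(initial=0) >= means.shape[0]:
        raise ValueError("missing emission mean for some hidden state")
    out = means[states]
    if sigma_tilde > 0:
        out = out + rng.normal(scale=sigma_tilde, size=states.shape[0])
    return out


def make_two_subsystem_benchmark(
    spec: BenchmarkSpec | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """2-D trajectory from a 2-state (x axis) and a 3-state (y axis) chain.

    The chains are sampled independently; the global system has 6 states.
    """
    if spec is None:
        spec = BenchmarkSpec.two_subsystem()
    if len(spec.transition_matrices) != 2 or tuple(
        t.shape[0] for t in spec.transition_matrices
    ) != (2, 3):
        raise ValueError("two-subsystem benchmark needs chains with 2 and 3 states")
    rng = np.random.default_rng(spec.seed)
    hidden, cols = [], []
    for T, mu in zip(spec.transition_matrices, spec.emission_means):
        s = sample_markov_chain(T, spec.n_steps, rng)
        hidden.append(s)
        cols.append(gaussian_emission(s, mu, spec.emission_width, rng))
    data = np.stack(cols, axis=1)
    return data, GroundTruth(spec=spec, hidden_states=hidden)


def make_hypercube_benchmark(
    spec: BenchmarkSpec | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Trajectory of pairwise-rotated 2-state chains plus noise dimensions.

    Chains 2k and 2k+1 emit into a common 2-D plane rotated by the spec's
    angle, so the informative coordinates mix two subsystems each;
    ``n_noise_dims`` i.i.d. Gaussian columns are appended.
    """
    if spec is None:
        spec = BenchmarkSpec.hypercube()
    n_chains = len(spec.transition_matrices)
    if n_chains % 2 != 0:
        raise ValueError("hypercube benchmark needs an even number of chains")
    rng = np.random.default_rng(spec.seed)
    hidden, emitted = [], []
    for T, mu in zip(spec.transition_matrices, spec.emission_means):
        s = sample_markov_chain(T, spec.n_steps, rng)
        hidden.append(s)
        emitted.append(gaussian_emission(s, mu, spec.emission_width, rng))
    a = spec.rotation_angle
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    cols = []
    for k in range(0, n_chains, 2):
        plane = rot @ np.stack([emitted[k], emitted[k + 1]], axis=0)
        cols.extend([plane[0], plane[1]])
    for _ in range(spec.n_noise_dims):
        cols.append(rng.normal(scale=spec.noise_width, size=spec.n_steps))
    data = np.stack(cols, axis=1)
    return data, GroundTruth(spec=spec, hidden_states=hidden)


def make_cooperative_control(
    n_steps: int = 50_000,
    seed: int = 0,
    emission_width: float = 0.2,
) -> tuple[np.ndarray, GroundTruth]:
    """Negative control: one cooperative 3-state process seen by both axes.

    A single global 3-state chain is emitted onto both features with
    different mode layouts (as if two structural regions both reported the
    same cooperative transition). Both coordinates carry real kinetics,
    but the dynamics cannot be decomposed into two independent
    subsystems — models trained on this data must fail the independence
    metrics.
    """
    T = three_state_matrix()
    mu_x = np.array([-1.0, 0.0, 1.0])
    mu_y = np.array([1.0, -1.0, 0.0])
    rng = np.random.default_rng(seed)
    s = sample_markov_chain(T, n_steps, rng)
    x = gaussian_emission(s, mu_x, emission_width, rng)
    y = gaussian_emission(s, mu_y, emission_width, rng)
    spec = BenchmarkSpec(
        transition_matrices=[T],
        emission_means=[mu_x],
        emission_width=emission_width,
        n_steps=n_steps,
        seed=seed,
    )
    return np.stack([x, y], axis=1), GroundTruth(spec=spec, hidden_states=[s])
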