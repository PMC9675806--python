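# ivamp

Decomposition of high-dimensional dynamical systems into approximately
independent Markovian subsystems, learned end to end from trajectory data.

Markov state models describe molecular kinetics through transitions
between global configuration states — but the number of global states
grows exponentially with system size, because large molecules contain
many nearly independent parts. `ivamp` learns, simultaneously:

* an **attention mask** G ∈ [0,1]^{D×N} that assigns input features
  (coordinates, residue–residue distances) to N subsystems, and
* a **fuzzy Markov state model per subsystem** — a neural network
  χ^i(x) with SoftMax output, whose time-lagged correlation matrices
  C00, C0τ, Cττ yield a Koopman model by whitened singular value
  decomposition, K̄ = C00^(−1/2) C0τ Cττ^(−1/2) = A K Bᵀ.

Training maximizes the pairwise global VAMP-E score of the Kronecker
construction (K^G = ⊗K^i, U^G = ⊗U^i, V^G = ⊗V^i) and penalizes
statistical dependence:

    L = −Σ_{i<j} R_E^{ij} + ξ Σ_{i<j} |R_E^{ij} − R_E^i R_E^j| / R_E^{ij}

For truly independent subsystems the global score factorizes,
R_E^G = Π_i R_E^i, and the constructed singular functions are orthonormal;
the deviations from these identities — M_U, M_V, M_UV, M_R — are computed
after training as quantitative independence tests. The package also ships
hidden-Markov benchmark generators (independent chains with Gaussian
emissions, rotated planes, noise dimensions), an implied-timescales lag
validation, residue-distance featurization for proteins, and a CLI.

It is written for practitioners of Markov state modeling who want an
interpretable, data-efficient decomposition of systems too large for a
single global kinetic model. The training core is a self-contained
numpy reverse-mode autodiff engine — no GPU or deep-learning framework
required.

## Worked example

Decompose the two-subsystem benchmark: a hidden 2-state chain (λ₂ = 0.90)
emitting to x and an independent hidden 3-state chain (λ₂ = 0.89,
λ₃ = 0.66) emitting to y.

```python
import numpy as np
import ivamp

data, truth = ivamp.make_two_subsystem_benchmark()   # 100000 x 2
cfg = ivamp.TrainingConfig(
    n_subsystems=2, states_per_subsystem=(2, 3), lag=1,
    epochs=20, restarts=4, seed=0,
)
model = ivamp.IVampnetModel(n_features=2, config=cfg)
history = ivamp.fit(model, data, cfg)

print(np.round(model.mask(), 2))
models, corrs = model.koopman_models(data)
for i, (m, c) in enumerate(zip(models, corrs)):
    T = ivamp.koopman_matrix(c)
    spec = ivamp.spectral_analysis(T, lag=1, imag_tol=1.0)
    print(f"subsystem {i} eigenvalues:", np.round(np.sort(spec.eigenvalues)[::-1], 3))

from ivamp.pipeline import independence_report
rep = independence_report(model, data[-10000:])
print(f"M_U={rep.m_u:.4f} M_V={rep.m_v:.4f} M_UV={rep.m_uv:.4f} M_R={rep.m_r:.4f}")
```

Output (about a minute on one CPU):

```
[[ 0.66 -0.  ]
 [ 0.    0.66]]
subsystem 0 eigenvalues: [1.  0.9]
subsystem 1 eigenvalues: [1.    0.878 0.643]
M_U=0.0076 M_V=0.0076 M_UV=0.0071 M_R=0.0026
```

The mask routes x to the 2-state subsystem and y to the 3-state subsystem
(0.66 is the maximum weight after the dummy column takes its share); the
subsystem eigenvalues recover the generating chains (0.90; 0.89 and
0.66) to within sampling error; and all four independence scores on
held-out data are below 0.01, confirming the learned subsystems are
statistically independent.

The same workflow from the shell:

```bash
ivamp generate two-subsystem --out bench2
ivamp train config.yaml --out results/
ivamp timescales results/model.npz bench2/trajectory.npy --lags 1,2,5,10
```

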