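"""End-to-end trainable model: attention mask + N parallel subsystem nets.

Each subsystem net is a multilayer perceptron with SoftMax output giving
fuzzy state assignments χ^i. Both lobes of a time-lagged pair share
parameters. Training minimizes the pairwise loss

    L = −Σ_{i<j} R_E^{ij} + ξ Σ_{i<j} |R_E^{ij} − R_E^i R_E^j| / R_E^{ij},

where R_E^i is the subsystem VAMP-E score (sum of squared singular values
of the whitened K̄^i) and R_E^{ij} is the VAMP-E score of the Kronecker
pair construction evaluated against the empirical pair correlations. The
loss is differentiated end to end (through whitening and SVD) with the
package's own reverse-mode engine and optimized with Adam.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .independence import TrainingConfig
from .koopman import CorrelationSet, KoopmanModel, estimate_correlations, whitened_svd
from .masking import ResidueMaskSpec, window_coverage_matrix

__all__ = ["SubsystemNet", "IVampnetModel", "fit", "transform"]


class SubsystemNet:
    """Fully connected ELU network with SoftMax output (fuzzy states)."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_states: int,
        rng: np.random.Generator,
    ):
        self.n_in = n_in
        self.n_states = n_states
        self.params: list[ad.Tensor] = []
        widths = [n_in, *hidden, n_states]
        self._layers = []
        for a, b in zip(widths[:-1], widths[1:]):
            w = ad.Tensor(rng.normal(scale=np.sqrt(2.0 / a), size=(a, b)), requires_grad=True)
            bias = ad.Tensor(np.zeros(b), requires_grad=True)
            self._layers.append((w, bias))
            self.params.extend([w, bias])

    def forward(self, y: ad.Tensor) -> ad.Tensor:
        h = y
        for w, b in self._layers[:-1]:
            h = ad.elu(ad.matmul(h, w) + b)
        w, b = self._layers[-1]
        return ad.softmax(ad.matmul(h, w) + b, axis=1)


class IVampnetModel:
    """Attention mask plus N parallel subsystem networks.

    The mask raw weights are trained jointly with the networks; at
    evaluation time the interpolation noise is disabled.
    """

    def __init__(
        self,
        n_features: int,
        config: TrainingConfig,
        residue_windows: ResidueMaskSpec | None = None,
    ):
        self.config = config
        self.n_features = n_features
        self.residue_windows = residue_windows
        rng = np.random.default_rng(config.seed)
        if residue_windows is not None:
            # residue mode: n_features is the residue count R; trainable
            # logits live on chain windows; subsystem nets see the R×R
            # attention-scaled contact map G_i G_j exp(−d_ij), flattened
            if residue_windows.n_residues != n_features:
                raise ValueError("residue window spec does not cover n_features residues")
            n_windows = residue_windows.window_weights.shape[0]
            self._coverage = window_coverage_matrix(
                n_features, n_windows, residue_windows.window_size, residue_windows.step
            )
            self.mask_raw = ad.Tensor(
                rng.normal(size=(n_windows, config.n_subsystems)), requires_grad=True
            )
            net_in = n_features * n_features
        else:
            # unit-scale random init gives each run a different initial
            # feature preference; fit() with restarts>1 exploits this to
            # escape poor mask/subsystem pairings
            self._coverage = None
            self.mask_raw = ad.Tensor(
                rng.normal(size=(n_features, config.n_subsystems)), requires_grad=True
            )
            net_in = n_features
        self.dummy_const = 1.0 / n_features
        self.nets = [
            SubsystemNet(net_in, config.hidden, n, rng)
            for n in config.states_per_subsystem
        ]
        self.sigma: float = 0.0 if config.sigma is None else config.sigma
        # feature standardization learned by fit()
        self.feature_mean = np.zeros(n_features)
        self.feature_scale = np.ones(n_features)
        self.mask_blend = 0.0  # annealing coefficient α, driven by fit()
        self._uniform_mask_cache: np.ndarray | None = None
        self._rng = rng  # noise / shuffling stream, advanced by fit()

    # -- parameters -----------------------------------------------------------
    @property
    def params(self) -> list[ad.Tensor]:
        out = [self.mask_raw]
        for net in self.nets:
            out.extend(net.params)
        return out

    # -- mask -----------------------------------------------------------------
    def _mask_pipeline(self, g1: ad.Tensor) -> ad.Tensor:
        g2 = ad.relu(g1 - self.config.theta)
        dummy = ad.Tensor(np.full((self.n_features, 1), self.dummy_const))
        g3 = ad.concat([g2, dummy], axis=1)
        g4 = g3 / ad.sum_(g3, axis=1, keepdims=True)
        return g4[:, : self.config.n_subsystems]

    def mask_tensor(self) -> ad.Tensor:
        if self.residue_windows is not None:
            gbar = ad.softmax(self.mask_raw, axis=0)
            # per-residue product of covering windows: exp(C @ log ḡ)
            g1 = ad.exp(ad.matmul(ad.Tensor(self._coverage), ad.log(gbar)))
        else:
            g1 = ad.softmax(self.mask_raw, axis=0)
        return self._mask_pipeline(g1)

    def _uniform_mask(self) -> np.ndarray:
        """Mask produced by all-equal raw logits (the annealing target)."""
        if self._uniform_mask_cache is None:
            saved = self.mask_raw.data
            self.mask_raw.data = np.zeros_like(saved)
            try:
                self._uniform_mask_cache = self.mask_tensor().data
            finally:
                self.mask_raw.data = saved
        return self._uniform_mask_cache

    def _blended_mask_tensor(self) -> ad.Tensor:
        """Training-time mask: anneals from uniform (α=1) to learned (α=0).

        While α > 0 every subsystem still sees every feature, so fuzzy
        state functions can form before the attention hardens; the learned
        mask takes over as α decays.
        """
        g = self.mask_tensor()
        a = self.mask_blend
        if a <= 0:
            return g
        return g * (1.0 - a) + a * self._uniform_mask()

    def mask(self) -> np.ndarray:
        """Current mask G ∈ [0,1]^{D×N} as a plain array."""
        return self.mask_tensor().data.copy()

    # -- forward --------------------------------------------------------------
    def _lobe(
        self, x: np.ndarray, g: ad.Tensor, training: bool, rng: np.random.Generator
    ) -> list[ad.Tensor]:
        sigma_eff = self.sigma * (1.0 - self.mask_blend) if training else 0.0
        chis = []
        if self.residue_windows is not None:
            r = self.n_features
            b = x.shape[0]
            contact = np.exp(-x)  # x holds per-frame R×R distance matrices
            contact[:, np.arange(r), np.arange(r)] = 0.0
            xs = ad.Tensor(contact)
            for i, net in enumerate(self.nets):
                gi = g[:, i : i + 1]  # (R, 1)
                pair_weight = gi.reshape(1, r, 1) * gi.reshape(1, 1, r)
                y = xs * pair_weight
                if training and sigma_eff > 0:
                    eps = ad.Tensor(rng.normal(size=contact.shape))
                    y = y + eps * (sigma_eff * (1.0 - pair_weight))
                chis.append(net.forward(y.reshape(b, r * r)))
            return chis
        xs = ad.Tensor((x - self.feature_mean) / self.feature_scale)
        for i, net in enumerate(self.nets):
            gi = g[:, i : i + 1].T  # (1, D), broadcasts over the batch
            y = xs * gi
            if training and sigma_eff > 0:
                eps = ad.Tensor(rng.normal(size=x.shape))
                y = y + eps * (sigma_eff * (1.0 - gi))
            chis.append(net.forward(y))
        return chis

    def forward(
        self,
        x_t: np.ndarray,
        x_tau: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[list[ad.Tensor], list[ad.Tensor]]:
        """Per-subsystem assignment pairs (χ^i(x_t), χ^i(x_{t+τ})).

        Both lobes share parameters and the same mask; in training mode
        independent noise is drawn for each lobe.
        """
        x_t = np.atleast_2d(x_t)
        x_tau = np.atleast_2d(x_tau)
        expected = (
            (self.n_features, self.n_features)
            if self.residue_windows is not None
            else (self.n_features,)
        )
        if x_t.shape[1:] != expected:
            raise ValueError(
                f"input frames have shape {x_t.shape[1:]}, model expects {expected}"
            )
        rng = rng or self._rng
        g = self._blended_mask_tensor() if training else self.mask_tensor()
        return self._lobe(x_t, g, training, rng), self._lobe(x_tau, g, training, rng)

    # -- evaluation -----------------------------------------------------------
    def transform(self, trajectory: np.ndarray, chunk: int = 65536) -> list[np.ndarray]:
        """Eval-mode state probabilities per subsystem (noise disabled)."""
        trajectory = np.atleast_2d(np.asarray(trajectory, dtype=np.float64))
        g = self.mask_tensor()
        outs = [[] for _ in self.nets]
        for start in range(0, trajectory.shape[0], chunk):
            x = trajectory[start : start + chunk]
            for i, chi in enumerate(self._lobe(x, g, training=False, rng=self._rng)):
                outs[i].append(chi.data)
        return [np.concatenate(o, axis=0) for o in outs]

    def koopman_models(
        self, trajectory: np.ndarray, lag: int | None = None
    ) -> tuple[list[KoopmanModel], list[CorrelationSet]]:
        """Per-subsystem whitened-SVD models estimated from a trajectory."""
        lag = self.config.lag if lag is None else lag
        chis = self.transform(trajectory)
        models, corrs = [], []
        for chi in chis:
            corr = estimate_correlations(chi[:-lag], chi[lag:], lag=lag)
            corrs.append(corr)
            models.append(whitened_svd(corr, epsilon=self.config.epsilon))
        return models, corrs

    # -- persistence ----------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {
            "mask_raw": self.mask_raw.data,
            "sigma": np.array(self.sigma),
            "feature_mean": self.feature_mean,
            "feature_scale": self.feature_scale,
        }
        for i, net in enumerate(self.nets):
            for j, p in enumerate(net.params):
                arrays[f"net{i}_p{j}"] = p.data
        np.savez(path, **arrays)

    def load(self, path: str) -> None:
        with np.load(path) as archive:
            self.mask_raw.data = archive["mask_raw"]
            self.sigma = float(archive["sigma"])
            self.feature_mean = archive["feature_mean"]
            self.feature_scale = archive["feature_scale"]
            for i, net in enumerate(self.nets):
                for j, p in enumerate(net.params):
                    p.data = archive[f"net{i}_p{j}"]

    def copy_parameters_from(self, other: "IVampnetModel") -> None:
        self.mask_raw.data = other.mask_raw.data.copy()
        self.sigma = other.sigma
        self.feature_mean = other.feature_mean.copy()
        self.feature_scale = other.feature_scale.copy()
        for net, onet in zip(self.nets, other.nets):
            for p, op in zip(net.params, onet.params):
                p.data = op.data.copy()


# -- differentiable score pieces ----------------------------------------------


def _diagonal(a: ad.Tensor) -> ad.Tensor:
    n = a.shape[0]
    return a[np.arange(n), np.arange(n)]


def _correlations_t(chi_t: ad.Tensor, chi_tau: ad.Tensor) -> tuple[ad.Tensor, ...]:
    L = chi_t.shape[0]
    return (
        ad.matmul(chi_t.T, chi_t) * (1.0 / L),
        ad.matmul(chi_t.T, chi_tau) * (1.0 / L),
        ad.matmul(chi_tau.T, chi_tau) * (1.0 / L),
    )


def _whitened_factors(
    c00: ad.Tensor, c0t: ad.Tensor, ctt: ad.Tensor, epsilon: float
) -> tuple[ad.Tensor, ad.Tensor, ad.Tensor, ad.Tensor]:
    """Differentiable whitened factors U, s, V of one subsystem."""
    n = c00.shape[0]
    reg0 = epsilon * float(np.trace(c00.data)) / n
    regt = epsilon * float(np.trace(ctt.data)) / n
    w0 = ad.sym_inv_sqrt(c00, reg0)
    wt = ad.sym_inv_sqrt(ctt, regt)
    kbar = ad.matmul(ad.matmul(w0, c0t), wt)
    a, s, b = ad.svd(kbar)
    u = ad.matmul(w0, a)
    v = ad.matmul(wt, b)
    return u, s, v


def _pair_kron(chi_i: ad.Tensor, chi_j: ad.Tensor) -> ad.Tensor:
    B, ni = chi_i.shape
    nj = chi_j.shape[1]
    prod = chi_i.reshape(B, ni, 1) * chi_j.reshape(B, 1, nj)
    return prod.reshape(B, ni * nj)


def _pair_score(
    u_i: ad.Tensor, s_i: ad.Tensor, v_i: ad.Tensor,
    u_j: ad.Tensor, s_j: ad.Tensor, v_j: ad.Tensor,
    c00: ad.Tensor, c0t: ad.Tensor, ctt: ad.Tensor,
) -> ad.Tensor:
    """VAMP-E score of the Kronecker pair construction (Eq. of R_E^{ij})."""
    ug = ad.kron2(u_i, u_j)
    vg = ad.kron2(v_i, v_j)
    ni, nj = s_i.shape[0], s_j.shape[0]
    sg = (s_i.reshape(ni, 1) * s_j.reshape(1, nj)).reshape(ni * nj)
    a = ad.matmul(ad.matmul(ug.T, c0t), vg)
    b = ad.matmul(ad.matmul(ug.T, c00), ug)
    c = ad.matmul(ad.matmul(vg.T, ctt), vg)
    first = 2.0 * ad.sum_(sg * _diagonal(a))
    sbs = sg.reshape(ni * nj, 1) * b * sg.reshape(1, ni * nj)
    second = ad.sum_(sbs * c.T)
    return first - second


def batch_loss(
    model: IVampnetModel,
    x_t: np.ndarray,
    x_tau: np.ndarray,
    xi: float,
    training: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[ad.Tensor, dict]:
    """Differentiable pairwise loss on one minibatch, plus diagnostics."""
    chis_t, chis_tau = model.forward(x_t, x_tau, training=training, rng=rng)
    n_sub = len(model.nets)
    factors, scores = [], []
    for chi_t, chi_tau in zip(chis_t, chis_tau):
        pop = chi_t.data.mean(axis=0)
        if pop.min() * chi_t.shape[0] < 1.0:
            warnings.warn(
                "a subsystem state is (almost) unpopulated in this batch; "
                "continuing with regularized correlations",
                RuntimeWarning,
                stacklevel=2,
            )
        c00, c0t, ctt = _correlations_t(chi_t, chi_tau)
        u, s, v = _whitened_factors(c00, c0t, ctt, model.config.epsilon)
        factors.append((u, s, v))
        scores.append(ad.sum_(s * s))
    if n_sub == 1:
        loss = -scores[0]
        return loss, {
            "scores": [scores[0].item()],
            "pair_scores": {},
            "penalty": 0.0,
        }
    loss_terms = []
    penalty_terms = []
    pair_scores = {}
    for i, j in itertools.combinations(range(n_sub), 2):
        chi_pair_t = _pair_kron(chis_t[i], chis_t[j])
        chi_pair_tau = _pair_kron(chis_tau[i], chis_tau[j])
        c00, c0t, ctt = _correlations_t(chi_pair_t, chi_pair_tau)
        r_ij = _pair_score(*factors[i], *factors[j], c00, c0t, ctt)
        pair_scores[(i, j)] = r_ij.item()
        loss_terms.append(-r_ij)
        penalty_terms.append(ad.abs_(r_ij - scores[i] * scores[j]) / r_ij)
    loss = loss_terms[0]
    for t in loss_terms[1:]:
        loss = loss + t
    penalty = penalty_terms[0]
    for t in penalty_terms[1:]:
        penalty = penalty + t
    if xi > 0:
        loss = loss + xi * penalty
    return loss, {
        "scores": [s.item() for s in scores],
        "pair_scores": pair_scores,
        "penalty": penalty.item(),
    }


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: list[ad.Tensor], lr: float | list[float] = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = [lr] * len(params) if np.isscalar(lr) else list(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr[i] * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def training_step(
    model: IVampnetModel,
    x_t: np.ndarray,
    x_tau: np.ndarray,
    optimizer: Adam,
    xi: float,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict]:
    """One gradient step on a minibatch; returns the loss value."""
    optimizer.zero_grad()
    loss, info = batch_loss(model, x_t, x_tau, xi, training=True, rng=rng)
    loss.backward()
    optimizer.step()
    return loss.item(), info


def make_optimizer(model: IVampnetModel) -> Adam:
    cfg = model.config
    lrs = [cfg.mask_lr] + [cfg.lr] * (len(model.params) - 1)
    return Adam(model.params, lr=lrs)


def _run_epochs(
    model: IVampnetModel,
    cfg: TrainingConfig,
    x_t: np.ndarray,
    x_tau: np.ndarray,
    x_t_val: np.ndarray,
    x_tau_val: np.ndarray,
    rng: np.random.Generator,
    opt: Adam,
    first_epoch: int,
    n_epochs: int,
) -> list[dict]:
    n_train = x_t.shape[0]
    n_batches = max(1, n_train // cfg.batch)
    warmup_epochs = max(1, int(np.ceil(cfg.epochs * cfg.xi_warmup)))
    rows = []
    for epoch in range(first_epoch, first_epoch + n_epochs):
        ramp = min(1.0, (epoch + 1) / warmup_epochs) if cfg.xi_warmup > 0 else 1.0
        xi = cfg.xi * ramp
        # mask annealing: uniform mask (and no noise) while frozen, then a
        # linear hand-over to the learned mask
        if epoch < cfg.mask_freeze_epochs:
            alpha = 1.0
        elif cfg.mask_anneal_epochs > 0:
            alpha = max(0.0, 1.0 - (epoch - cfg.mask_freeze_epochs) / cfg.mask_anneal_epochs)
        else:
            alpha = 0.0
        model.mask_blend = alpha
        opt.lr[0] = 0.0 if alpha >= 1.0 else cfg.mask_lr
        order = rng.permutation(n_train)
        ep_loss, ep_pen, ep_scores = [], [], []
        for b in range(n_batches):
            idx = order[b * cfg.batch : (b + 1) * cfg.batch]
            if idx.size < 2:
                continue
            loss_val, info = training_step(model, x_t[idx], x_tau[idx], opt, xi, rng)
            ep_loss.append(loss_val)
            ep_pen.append(info["penalty"])
            ep_scores.append(info["scores"])
        row = {
            "epoch": epoch,
            "loss": float(np.mean(ep_loss)),
            "penalty": float(np.mean(ep_pen)),
            "xi": xi,
        }
        for i, s in enumerate(np.mean(ep_scores, axis=0)):
            row[f"score_{i}"] = float(s)
        if x_t_val.shape[0] > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _, val_info = batch_loss(model, x_t_val, x_tau_val, xi, training=False)
            for i, s in enumerate(val_info["scores"]):
                row[f"val_score_{i}"] = float(s)
        rows.append(row)
    return rows


def fit(
    model: IVampnetModel,
    trajectory: np.ndarray,
    config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Train on a feature trajectory; returns the per-epoch history.

    The trajectory is split into time-lagged pairs at the configured lag;
    the last ``validation_fraction`` (contiguous block) is held out and
    per-epoch subsystem scores are recorded on it. Features are
    standardized internally (stored on the model) unless disabled.

    With ``restarts > 1``, several candidates differing in their random
    initialization are probe-trained for ``probe_epochs`` epochs and the
    one with the lowest training loss is trained to completion — the loss
    separates good from poor mask/subsystem pairings early, so this
    escapes the local optima that a single run can fall into.
    Deterministic given the config seed.
    """
    cfg = config or model.config
    trajectory = np.atleast_2d(np.asarray(trajectory, dtype=np.float64))
    lag = cfg.lag
    if trajectory.shape[0] <= lag:
        raise ValueError("trajectory shorter than the lag time")
    if cfg.standardize and model.residue_windows is None:
        model.feature_mean = trajectory.mean(axis=0)
        scale = trajectory.std(axis=0)
        model.feature_scale = np.where(scale > 0, scale, 1.0)
        std_mean = 1.0
    else:
        # residue mode feeds attention-scaled contact maps; standardizing
        # them would distort the G_i G_j exp(−d_ij) structure
        model.feature_mean = np.zeros(model.n_features)
        model.feature_scale = np.ones(model.n_features)
        std_mean = float(np.mean(trajectory.std(axis=0)))
    model.sigma = 0.15 * std_mean if cfg.sigma is None else cfg.sigma
    x_t_all, x_tau_all = trajectory[:-lag], trajectory[lag:]
    n_pairs = x_t_all.shape[0]
    n_train = int(round(n_pairs * (1.0 - cfg.validation_fraction)))
    x_t, x_tau = x_t_all[:n_train], x_tau_all[:n_train]
    x_t_val, x_tau_val = x_t_all[n_train:], x_tau_all[n_train:]

    probe = min(cfg.probe_epochs, cfg.epochs) if cfg.restarts > 1 else 0
    rows: list[dict]
    if probe:
        candidates = []
        for k in range(cfg.restarts):
            sub_cfg = dataclasses.replace(cfg, seed=cfg.seed + 1000 * k)
            cand = IVampnetModel(model.n_features, sub_cfg, residue_windows=model.residue_windows)
            cand.feature_mean = model.feature_mean.copy()
            cand.feature_scale = model.feature_scale.copy()
            cand.sigma = model.sigma
            cand_rng = np.random.default_rng(sub_cfg.seed + 1)
            cand._rng = cand_rng
            cand_opt = make_optimizer(cand)
            cand_rows = _run_epochs(
                cand, cfg, x_t, x_tau, x_t_val, x_tau_val, cand_rng, cand_opt, 0, probe
            )
            candidates.append((cand_rows[-1]["loss"], k, cand, cand_rng, cand_opt, cand_rows))
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, _, best, rng, opt, rows = candidates[0]
        model.copy_parameters_from(best)
        # keep training the winner's parameter tensors, then copy back
        rows += _run_epochs(
            best, cfg, x_t, x_tau, x_t_val, x_tau_val, rng, opt, probe, cfg.epochs - probe
        )
        model.copy_parameters_from(best)
        model._rng = rng
    else:
        rng = np.random.default_rng(cfg.seed + 1)
        model._rng = rng
        opt = make_optimizer(model)
        rows = _run_epochs(
            model, cfg, x_t, x_tau, x_t_val, x_tau_val, rng, opt, 0, cfg.epochs
        )
    model.mask_blend = 0.0
    return pd.DataFrame(rows)


def transform(model: IVampnetModel, trajectory: np.ndarray) -> list[np.ndarray]:
    """Eval-mode per-subsystem state-probability time series."""
    return model.transform(trajectory)
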