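"""End-to-end model: forward contracts, loss consistency, training, transform."""

import warnings

import numpy as np
import pytest

import ivamp
from ivamp.independence import TrainingConfig, construct_global_model, global_correlations, global_vamp_e
from ivamp.koopman import estimate_correlations, koopman_matrix, vamp_e_score, whitened_svd
from ivamp.model import Adam, IVampnetModel, batch_loss, fit, make_optimizer, training_step


@pytest.fixture(scope="module")
def small_data():
    data, _ = ivamp.make_two_subsystem_benchmark(
        ivamp.BenchmarkSpec.two_subsystem(n_steps=4000, seed=3)
    )
    return data


def _config(**kw):
    defaults = dict(
        n_subsystems=2, states_per_subsystem=(2, 3), lag=1, xi=1.0,
        batch=512, epochs=2, seed=0, hidden=(16, 16),
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestForward:
    def test_outputs_are_probability_vectors(self, small_data):
        model = IVampnetModel(2, _config())
        chis_t, chis_tau = model.forward(small_data[:64], small_data[1:65])
        assert len(chis_t) == 2
        for chi, n in zip(chis_t, (2, 3)):
            assert chi.shape == (64, n)
            np.testing.assert_allclose(chi.data.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(chi.data >= 0)

    def test_eval_mode_lobes_share_weights(self, small_data):
        model = IVampnetModel(2, _config())
        x = small_data[:32]
        chis_t, chis_tau = model.forward(x, x, training=False)
        for a, b in zip(chis_t, chis_tau):
            np.testing.assert_array_equal(a.data, b.data)

    def test_dimension_mismatch_raises(self, small_data):
        model = IVampnetModel(2, _config())
        with pytest.raises(ValueError, match="expects"):
            model.forward(np.ones((4, 5)), np.ones((4, 5)))

    def test_mask_entries_bounded(self):
        model = IVampnetModel(6, _config())
        g = model.mask()
        assert g.shape == (6, 2)
        assert np.all(g >= 0) and np.all(g <= 1)


class TestBatchLoss:
    def test_matches_independence_module_at_xi_zero(self, small_data):
        # the differentiable loss must equal −R_E^{12} computed by the
        # independent numpy route on the same batch (no noise)
        model = IVampnetModel(2, _config())
        x_t, x_tau = small_data[:-1], small_data[1:]
        loss, _ = batch_loss(model, x_t, x_tau, xi=0.0, training=False)
        chis_t, chis_tau = model.forward(x_t, x_tau, training=False)
        models, scores = [], []
        for ct, ctau in zip(chis_t, chis_tau):
            corr = estimate_correlations(ct.data, ctau.data, lag=1)
            m = whitened_svd(corr)
            models.append(m)
            scores.append(vamp_e_score(m, corr))
        constr = construct_global_model(models)
        gcorr = global_correlations(
            [c.data for c in chis_t], [c.data for c in chis_tau], lag=1
        )
        assert loss.item() == pytest.approx(-global_vamp_e(constr, gcorr), rel=1e-9)

    def test_gradients_finite_at_random_init(self, small_data):
        model = IVampnetModel(2, _config(seed=5))
        model.sigma = 0.2
        loss, _ = batch_loss(
            model, small_data[:512], small_data[1:513], xi=1.0, training=True,
            rng=np.random.default_rng(0),
        )
        loss.backward()
        for p in model.params:
            assert p.grad is not None
            assert np.all(np.isfinite(p.grad))

    def test_single_subsystem_loss_is_own_score(self, small_data):
        cfg = _config(n_subsystems=1, states_per_subsystem=(3,))
        model = IVampnetModel(2, cfg)
        loss, info = batch_loss(model, small_data[:-1], small_data[1:], xi=2.0,
                                training=False)
        assert loss.item() == pytest.approx(-info["scores"][0])
        assert info["penalty"] == 0.0


class TestTrainingStep:
    def test_loss_decreases_over_training(self, small_data):
        cfg = _config(epochs=1)
        model = IVampnetModel(2, cfg)
        model.sigma = 0.15
        opt = make_optimizer(model)
        rng = np.random.default_rng(2)
        x_t, x_tau = small_data[:-1], small_data[1:]
        losses = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for step in range(200):
                idx = rng.integers(0, x_t.shape[0], size=cfg.batch)
                val, _ = training_step(model, x_t[idx], x_tau[idx], opt, xi=1.0, rng=rng)
                losses.append(val)
        assert np.mean(losses[-20:]) < np.mean(losses[:20]) - 0.1

    def test_parameters_change(self, small_data):
        model = IVampnetModel(2, _config())
        opt = make_optimizer(model)
        before = [p.data.copy() for p in model.params]
        training_step(model, small_data[:512], small_data[1:513], opt, xi=0.0,
                      rng=np.random.default_rng(0))
        changed = [not np.array_equal(a, p.data) for a, p in zip(before, model.params)]
        assert any(changed)


class TestFit:
    def test_bit_reproducible_given_seed(self, small_data):
        runs = []
        for _ in range(2):
            cfg = _config(epochs=2, seed=11)
            model = IVampnetModel(2, cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                hist = fit(model, small_data, cfg)
            runs.append((hist, [p.data.copy() for p in model.params]))
        (h1, p1), (h2, p2) = runs
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(h1["loss"].values, h2["loss"].values)

    def test_history_columns(self, small_data):
        cfg = _config(epochs=2)
        model = IVampnetModel(2, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hist = fit(model, small_data, cfg)
        for col in ("epoch", "loss", "penalty", "xi", "score_0", "score_1",
                    "val_score_0", "val_score_1"):
            assert col in hist.columns
        assert len(hist) == 2

    def test_trajectory_shorter_than_lag_rejected(self):
        cfg = _config(lag=100)
        model = IVampnetModel(2, cfg)
        with pytest.raises(ValueError, match="lag"):
            fit(model, np.ones((50, 2)), cfg)

    def test_restart_selection_prefers_lower_loss(self, small_data):
        cfg = _config(epochs=3, restarts=2, probe_epochs=1, seed=4)
        model = IVampnetModel(2, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hist = fit(model, small_data, cfg)
        assert len(hist) == 3  # probe epoch + remaining epochs of the winner


class TestTransform:
    def test_shapes_and_row_sums(self, small_data):
        model = IVampnetModel(2, _config())
        chis = model.transform(small_data)
        assert [c.shape for c in chis] == [(4000, 2), (4000, 3)]
        for c in chis:
            np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-8)

    def test_constant_input_gives_constant_output(self):
        model = IVampnetModel(2, _config())
        chis = model.transform(np.ones((10, 2)))
        for c in chis:
            np.testing.assert_allclose(c, np.broadcast_to(c[0], c.shape))

    def test_roundtrip_koopman_consistency(self, small_data):
        # transform → correlations → koopman matrix equals koopman_models()
        model = IVampnetModel(2, _config())
        chis = model.transform(small_data)
        models, corrs = model.koopman_models(small_data)
        for chi, corr in zip(chis, corrs):
            again = estimate_correlations(chi[:-1], chi[1:], lag=1)
            np.testing.assert_allclose(
                koopman_matrix(again), koopman_matrix(corr), atol=1e-12
            )

    def test_save_load_roundtrip(self, small_data, tmp_path):
        cfg = _config(epochs=1)
        model = IVampnetModel(2, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit(model, small_data, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = IVampnetModel(2, _config(seed=99))
        clone.load(path)
        np.testing.assert_array_equal(
            model.transform(small_data[:50])[0], clone.transform(small_data[:50])[0]
        )


class TestResidueMode:
    """Windowed residue attention driving distance-scaled contact features."""

    @staticmethod
    def _synthetic_distances(n_frames=1200, seed=0):
        # two 4-residue blocks, each opened/closed by an independent hidden
        # 2-state chain; inter-block distances stay constant
        from ivamp.benchmarks import sample_markov_chain, two_state_matrix

        rng = np.random.default_rng(seed)
        a = sample_markov_chain(two_state_matrix(0.95), n_frames, rng)
        b = sample_markov_chain(two_state_matrix(0.90), n_frames, rng)
        d = np.full((n_frames, 8, 8), 2.0)
        for block, chain in (((0, 4), a), ((4, 8), b)):
            lo, hi = block
            intra = np.where(chain == 0, 0.2, 1.0)
            d[:, lo:hi, lo:hi] = intra[:, None, None]
        d += rng.normal(scale=0.01, size=d.shape)
        d = np.abs((d + d.transpose(0, 2, 1)) / 2)
        idx = np.arange(8)
        d[:, idx, idx] = 0.0
        return d

    @staticmethod
    def _residue_model(seed=0, epochs=2):
        from ivamp.masking import ResidueMaskSpec

        spec = ResidueMaskSpec(
            np.zeros((3, 2)), window_size=4, step=2, n_residues=8, theta=0.0
        )
        cfg = TrainingConfig(
            n_subsystems=2, states_per_subsystem=(2, 2), lag=1, xi=1.0,
            batch=256, epochs=epochs, seed=seed, hidden=(16,), theta=0.0,
        )
        return IVampnetModel(8, cfg, residue_windows=spec), cfg

    def test_forward_contract(self):
        model, _ = self._residue_model()
        d = self._synthetic_distances(n_frames=40)
        chis_t, _ = model.forward(d[:-1], d[1:])
        for chi in chis_t:
            assert chi.shape == (39, 2)
            np.testing.assert_allclose(chi.data.sum(axis=1), 1.0, atol=1e-6)
        assert model.mask().shape == (8, 2)

    def test_wrong_frame_shape_rejected(self):
        model, _ = self._residue_model()
        with pytest.raises(ValueError, match="expects"):
            model.forward(np.ones((5, 8)), np.ones((5, 8)))

    def test_gradients_finite(self):
        model, _ = self._residue_model()
        model.sigma = 0.1
        d = self._synthetic_distances(n_frames=80)
        loss, _ = batch_loss(model, d[:-1], d[1:], xi=1.0, training=True,
                             rng=np.random.default_rng(0))
        loss.backward()
        for p in model.params:
            assert p.grad is not None and np.all(np.isfinite(p.grad))

    def test_training_reduces_loss(self):
        model, cfg = self._residue_model(epochs=4)
        d = self._synthetic_distances()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hist = fit(model, d, cfg)
        assert hist.loss.iloc[-1] < hist.loss.iloc[0]


class TestAdam:
    def test_minimizes_quadratic(self):
        from ivamp import _autodiff as ad

        x = ad.Tensor(np.array([3.0, -2.0]), requires_grad=True)
        opt = Adam([x], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = ad.sum_(x * x)
            loss.backward()
            opt.step()
        np.testing.assert_allclose(x.data, 0.0, atol=1e-3)
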