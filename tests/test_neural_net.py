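"""MLP forward/backward correctness, training protocol, ensembles, sweeps."""

import numpy as np
import pytest
from scipy.special import expit

from ascoh import neural_net as nn
from ascoh.errors import DegenerateCohortError


def _separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(-2.0, 0.3, size=(half, 2)),
                   rng.normal(+2.0, 0.3, size=(n - half, 2))])
    y = np.repeat([0, 1], [half, n - half])
    perm = rng.permutation(n)
    return X[perm], y[perm]


def _finite_diff_grads(model, X, y, eps=1e-6):
    grads = []
    for w in model.weights + model.biases:
        g = np.zeros_like(w)
        it = np.nditer(w, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = w[idx]
            w[idx] = orig + eps
            lp = nn.mse_loss(model, X, y)
            w[idx] = orig - eps
            lm = nn.mse_loss(model, X, y)
            w[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads


def _analytic_grads(model, X, y):
    before = model.copy()
    updated, _ = nn.train_step(model.copy(), X, y, learning_rate=1.0)
    return [(b - a) for a, b in
            zip(updated.weights + updated.biases, before.weights + before.biases)]


class TestPrepareInputs:
    def test_full_length_binning_is_identity_up_to_standardization(self):
        rng = np.random.default_rng(0)
        mats = [rng.normal(size=50) for _ in range(6)]
        X, tr = nn.prepare_inputs(mats, feature_len=50)
        recon = X * tr.std + tr.mean
        np.testing.assert_allclose(recon, np.vstack(mats), atol=1e-12)

    def test_constant_spectrum_bins_to_constants(self):
        X, tr = nn.prepare_inputs([np.ones(100), np.full(100, 2.0)], feature_len=10)
        recon = X * tr.std + tr.mean
        np.testing.assert_allclose(recon[0], 1.0)
        np.testing.assert_allclose(recon[1], 2.0)

    def test_block_average_matches_explicit_means(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20000)
        X, tr = nn.prepare_inputs([x, rng.normal(size=20000)], feature_len=400)
        recon = (X * tr.std + tr.mean)[0]
        expected = x.reshape(400, 50).mean(axis=1)
        np.testing.assert_allclose(recon, expected, atol=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            nn.prepare_inputs([np.ones(10), np.ones(12)], feature_len=5)

    def test_transform_reusable_on_new_spectra(self):
        rng = np.random.default_rng(2)
        train = [rng.normal(size=100) for _ in range(4)]
        _, tr = nn.prepare_inputs(train, feature_len=20)
        new = rng.normal(size=(2, 100))
        assert tr.apply(new).shape == (2, 20)


class TestInitAndForward:
    def test_init_deterministic_and_bounded(self):
        cfg = nn.MlpConfig(input_dim=7, hidden_layers=(5, 3))
        m1 = nn.init_model(cfg, np.random.default_rng(9))
        m2 = nn.init_model(cfg, np.random.default_rng(9))
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
            fan_in = w1.shape[0]
            assert np.max(np.abs(w1)) < 1.0 / np.sqrt(fan_in)
        assert all(np.all(b == 0) for b in m1.biases)

    def test_zero_weights_output_half(self):
        cfg = nn.MlpConfig(input_dim=4, hidden_layers=(3,))
        model = nn.init_model(cfg, np.random.default_rng(0))
        for w in model.weights:
            w[:] = 0.0
        out = nn.forward(model, np.random.default_rng(1).normal(size=(5, 4)))
        np.testing.assert_allclose(out, 0.5)

    def test_hand_computed_two_input_single_hidden(self):
        model = nn.MlpModel(weights=[np.array([[0.3], [-0.2]]), np.array([[0.7]])],
                            biases=[np.array([0.1]), np.array([-0.4])])
        x = np.array([[1.5, 2.0]])
        h = expit(0.3 * 1.5 - 0.2 * 2.0 + 0.1)
        expected = expit(0.7 * h - 0.4)
        assert nn.forward(model, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_outputs_strictly_inside_unit_interval(self):
        cfg = nn.MlpConfig(input_dim=3, hidden_layers=(4,))
        model = nn.init_model(cfg, np.random.default_rng(2))
        out = nn.forward(model, np.random.default_rng(3).normal(size=(20, 3)))
        assert np.all((out > 0) & (out < 1))

    def test_hidden_node_permutation_symmetry(self):
        cfg = nn.MlpConfig(input_dim=3, hidden_layers=(5,))
        model = nn.init_model(cfg, np.random.default_rng(4))
        X = np.random.default_rng(5).normal(size=(8, 3))
        base = nn.forward(model, X)
        perm = np.random.default_rng(6).permutation(5)
        permuted = nn.MlpModel(
            weights=[model.weights[0][:, perm], model.weights[1][perm, :]],
            biases=[model.biases[0][perm], model.biases[1]])
        np.testing.assert_allclose(nn.forward(permuted, X), base, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(2,))
        model = nn.init_model(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="finite"):
            nn.forward(model, np.array([[1.0, np.nan]]))


class TestTrainStep:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            dims = (int(rng.integers(1, 4)),
                    tuple(int(v) for v in rng.integers(1, 4, size=rng.integers(1, 3))))
            cfg = nn.MlpConfig(input_dim=dims[0], hidden_layers=dims[1])
            model = nn.init_model(cfg, rng)
            X = rng.normal(size=(4, dims[0]))
            y = rng.integers(0, 2, size=4)
            analytic = _analytic_grads(model, X, y)
            numeric = _finite_diff_grads(model.copy(), X, y)
            for a, g in zip(analytic, numeric):
                np.testing.assert_allclose(a, g, rtol=1e-5, atol=1e-8)

    def test_zero_learning_rate_leaves_model_unchanged(self):
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(3,))
        model = nn.init_model(cfg, np.random.default_rng(1))
        before = model.copy()
        nn.train_step(model, np.ones((2, 2)), np.array([0, 1]), learning_rate=0.0)
        for w0, w1 in zip(before.weights, model.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_single_weight_delta_rule(self):
        # logistic unit (no hidden layer): dL/dw = 2(y-t) y(1-y) x
        model = nn.MlpModel(weights=[np.array([[0.5]])], biases=[np.array([0.2])])
        x, t, lr = 1.3, 1.0, 0.1
        y = expit(0.5 * x + 0.2)
        grad_w = 2 * (y - t) * y * (1 - y) * x
        grad_b = 2 * (y - t) * y * (1 - y)
        nn.train_step(model, np.array([[x]]), np.array([t]), learning_rate=lr)
        assert model.weights[0][0, 0] == pytest.approx(0.5 - lr * grad_w, abs=1e-12)
        assert model.biases[0][0] == pytest.approx(0.2 - lr * grad_b, abs=1e-12)

    def test_loss_non_increasing_with_small_steps(self):
        rng = np.random.default_rng(7)
        cfg = nn.MlpConfig(input_dim=3, hidden_layers=(4,))
        model = nn.init_model(cfg, rng)
        X = rng.normal(size=(10, 3))
        y = rng.integers(0, 2, size=10)
        losses = [nn.train_step(model, X, y, learning_rate=0.01)[1] for _ in range(11)]
        assert all(l1 <= l0 + 1e-12 for l0, l1 in zip(losses, losses[1:]))


class TestTrainRun:
    def test_split_sizes_use_floor_rule(self):
        X = np.random.default_rng(0).normal(size=(45, 2))
        y = np.tile([0, 1], 23)[:45]
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(2,), max_epochs=2)
        res = nn.train_run(X, y, cfg, np.random.default_rng(1))
        assert (res.n_train, res.n_val, res.n_test) == (33, 6, 6)

    def test_separable_data_trains_to_low_error(self):
        X, y = _separable_data()
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(12,), learning_rate=0.5,
                           max_epochs=2000, patience_epochs=25)
        res = nn.train_run(X, y, cfg, np.random.default_rng(2))
        assert res.test_error < 0.05

    def test_one_class_cohort_exhausts_split_retries(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.zeros(20)
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(2,))
        with pytest.raises(DegenerateCohortError):
            nn.train_run(X, y, cfg, np.random.default_rng(0))


class TestRunEnsemble:
    def test_single_run_aggregates_equal_that_run(self):
        X, y = _separable_data(n=30, seed=3)
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(4,), n_runs=1, seed=5,
                           max_epochs=50)
        ens = nn.run_ensemble(X, y, cfg)
        assert len(ens.runs) == 1
        assert ens.mean_error == ens.runs[0].test_error
        assert ens.error_range == (ens.runs[0].test_error, ens.runs[0].test_error)

    def test_fixed_master_seed_reproduces_ensemble(self):
        X, y = _separable_data(n=30, seed=4)
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(3,), n_runs=4, seed=8,
                           max_epochs=30)
        e1, e2 = nn.run_ensemble(X, y, cfg), nn.run_ensemble(X, y, cfg)
        assert [r.test_error for r in e1.runs] == [r.test_error for r in e2.runs]
        assert e1.mean_auc == e2.mean_auc


class TestConvergenceRule:
    def _ensemble_from_errors(self, errors):
        runs = tuple(nn.RunResult(e, 0.5, 1, 1, 1, 1, False) for e in errors)
        errors = np.asarray(errors, float)
        return nn.RunEnsemble(runs=runs, mean_error=errors.mean(),
                              error_sd=errors.std(ddof=1),
                              error_range=(errors.min(), errors.max()),
                              mean_auc=0.5, pooled_auc=0.5, n_degenerate_auc=0)

    def test_identical_errors_converged(self):
        check = nn.check_run_convergence(self._ensemble_from_errors([0.3] * 10))
        assert check.converged

    def test_uniform_errors_not_converged(self):
        # uniform on [0,1]: SD ~ 0.289 >> 0.1 * range
        errors = np.random.default_rng(0).uniform(0, 1, size=500)
        check = nn.check_run_convergence(self._ensemble_from_errors(errors))
        assert not check.converged
        assert check.error_sd == pytest.approx(np.sqrt(1 / 12), abs=0.03)

    def test_two_runs_warns(self):
        with pytest.warns(UserWarning, match="2 runs"):
            nn.check_run_convergence(self._ensemble_from_errors([0.2, 0.2]))


class TestArchitectureSweep:
    def test_degenerate_grid_reduces_to_single_ensemble(self):
        X, y = _separable_data(n=30, seed=6)
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(12,), n_runs=3, seed=13,
                           max_epochs=30)
        surface = nn.architecture_sweep({450.0: (X, y)}, node_grid=[12],
                                        depth_grid=[1], config=cfg)
        assert surface.mean_error.shape == (1, 1, 1)
        cell_seed = np.random.SeedSequence((13, 0, 0, 0)).generate_state(1)[0] % (2**31)
        expected = nn.run_ensemble(X, y, nn.MlpConfig(
            input_dim=2, hidden_layers=(12,), n_runs=3, seed=cell_seed, max_epochs=30))
        assert surface.mean_error[0, 0, 0] == expected.mean_error
        assert surface.mean_auc[0, 0, 0] == expected.mean_auc

    def test_difference_surfaces_use_single_minus_deeper(self):
        X, y = _separable_data(n=30, seed=7)
        cfg = nn.MlpConfig(input_dim=2, hidden_layers=(2,), n_runs=2, seed=3,
                           max_epochs=20)
        surface = nn.architecture_sweep({400.0: (X, y)}, node_grid=[2, 4],
                                        depth_grid=[1, 2], config=cfg)
        d_err, d_auc = surface.diff_vs_single_layer(2)
        np.testing.assert_allclose(d_err, surface.mean_error[0] - surface.mean_error[1])
        np.testing.assert_allclose(d_auc, surface.mean_auc[0] - surface.mean_auc[1])

    def test_empty_grids_rejected(self):
        with pytest.raises(ValueError):
            nn.architecture_sweep({}, [12], [1],
                                  nn.MlpConfig(input_dim=2, hidden_layers=(2,)))
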