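"""Network construction, the forward pass against an explicit loop oracle,
training behaviour, and the linear/elastic-net baseline."""

import numpy as np
import pytest

from nnprs.nets import (
    NetworkSpec,
    TrainConfig,
    build_autoencoder,
    build_mlp,
    fit_linear,
    predict_ae_mlp,
    relu,
    train_regressor,
)


def _forward_oracle(net, X):
    """Per-layer forward pass with explicit Python loops."""
    acts = net.spec.activations
    out = []
    for x in X:
        v = list(x)
        for l, (W, b) in enumerate(zip(net.weights, net.biases)):
            if net.spec.skip_input_to_last_hidden and l == net.n_layers - 1:
                v = v + list(x)
            z = []
            for j in range(W.shape[1]):
                acc = b[j]
                for i in range(W.shape[0]):
                    acc += v[i] * W[i, j]
                z.append(acc)
            if acts[l] == "relu":
                v = [max(0.0, u) for u in z]
            elif acts[l] == "linear":
                v = z
            else:
                v = [2.0 / (1.0 + np.exp(-u)) for u in z]
        out.append(v)
    return np.array(out)


def test_relu_values():
    assert relu(-2.0) == 0.0
    assert relu(0.0) == 0.0
    assert relu(3.5) == 3.5
    np.testing.assert_array_equal(relu(np.array([-1.0, 2.0])), [0.0, 2.0])


class TestBuildMlp:
    def test_standard_layer_shapes(self):
        net = build_mlp(67)
        assert [w.shape for w in net.weights] == [(67, 50), (50, 30), (30, 20), (20, 1)]

    def test_small_sketch_shapes(self):
        net = build_mlp(5, hidden_widths=(4, 3))
        assert [w.shape for w in net.weights] == [(5, 4), (4, 3), (3, 1)]

    def test_seed_reproducibility(self):
        a, b = build_mlp(8, seed=4), build_mlp(8, seed=4)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        c = build_mlp(8, seed=5)
        assert not np.array_equal(a.weights[0], c.weights[0])

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_width=5, hidden_widths=(4, 0))


class TestForward:
    @pytest.mark.parametrize("skip", [False, True])
    def test_matches_loop_oracle(self, rng, skip):
        net = build_mlp(6, hidden_widths=(5, 4), seed=1, skip_input_to_last_hidden=skip)
        X = rng.uniform(0, 2, size=(3, 6))
        np.testing.assert_allclose(net.forward(X), _forward_oracle(net, X), atol=1e-10)

    def test_autoencoder_matches_loop_oracle(self, rng):
        ae = build_autoencoder(4, 6, seed=2)
        X = rng.uniform(0, 2, size=(3, 4))
        np.testing.assert_allclose(ae.forward(X), _forward_oracle(ae, X), atol=1e-10)

    def test_wrong_input_width_rejected(self, rng):
        net = build_mlp(6)
        with pytest.raises(ValueError, match="input width"):
            net.forward(rng.normal(size=(2, 5)))


class TestAutoencoderStructure:
    def test_shapes_57_to_67(self):
        ae = build_autoencoder(57, 67)
        assert [w.shape for w in ae.weights] == [(57, 67), (67, 67), (67, 67)]

    def test_outputs_in_open_interval_0_2(self, rng):
        ae = build_autoencoder(5, 8, seed=0)
        out = ae.forward(rng.uniform(0, 2, size=(50, 5)))
        assert out.min() > 0.0 and out.max() < 2.0

    def test_zero_preactivation_maps_to_one(self):
        ae = build_autoencoder(3, 4, seed=0)
        for w in ae.weights:
            w[:] = 0.0
        for b in ae.biases:
            b[:] = 0.0
        np.testing.assert_allclose(ae.forward(np.zeros((1, 3))), np.ones((1, 4)))

    def test_input_exceeding_full_rejected(self):
        with pytest.raises(ValueError):
            build_autoencoder(10, 5)


class TestTraining:
    def test_constant_target_learned(self, rng):
        X = rng.uniform(0, 2, size=(1000, 4))
        y = np.full(1000, 3.2)
        net = build_mlp(4, seed=0)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=8, eval_every=500, seed=0)
        train_regressor(net, X[:800], y[:800], X[800:], y[800:], cfg)
        assert np.mean((net.predict(X[800:]) - 3.2) ** 2) < 1e-3

    def test_run_to_run_reproducible(self, rng):
        X = rng.uniform(0, 2, size=(300, 3))
        y = X @ np.array([1.0, -0.5, 2.0])
        nets = []
        for _ in range(2):
            net = build_mlp(3, seed=7)
            cfg = TrainConfig(max_epochs=2, eval_every=50, seed=7)
            train_regressor(net, X[:200], y[:200], X[200:], y[200:], cfg)
            nets.append(net)
        for wa, wb in zip(nets[0].weights, nets[1].weights):
            np.testing.assert_array_equal(wa, wb)
        assert len(nets[0].history) == len(nets[1].history)

    def test_validation_never_worse_than_init(self, rng):
        X = rng.uniform(0, 2, size=(500, 5))
        y = X.sum(axis=1)
        net = build_mlp(5, seed=3)
        init_loss = np.mean((net.predict(X[400:]) - y[400:]) ** 2)
        cfg = TrainConfig(max_epochs=1, eval_every=40, seed=3)
        train_regressor(net, X[:400], y[:400], X[400:], y[400:], cfg)
        assert np.mean((net.predict(X[400:]) - y[400:]) ** 2) <= init_loss

    def test_multi_output_history_per_column(self, rng):
        X = rng.uniform(0, 2, size=(600, 4))
        Y = np.column_stack([X.sum(axis=1), X[:, 0] - X[:, 1]])
        net = build_mlp(4, output_width=2, seed=1)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=6, eval_every=300, seed=1)
        train_regressor(net, X[:500], Y[:500], X[500:], Y[500:], cfg)
        assert all(len(np.atleast_1d(h["val_loss"])) == 2 for h in net.history)
        first, last = net.history[0]["val_loss"], net.history[-1]["val_loss"]
        assert (last < first).all()

    def test_shape_mismatch_rejected(self, rng):
        net = build_mlp(4)
        X = rng.uniform(0, 2, size=(50, 4))
        with pytest.raises(ValueError, match="one column per output"):
            train_regressor(net, X, np.zeros((50, 2)), X, np.zeros((50, 2)),
                            TrainConfig(max_epochs=1))


class TestLinear:
    def test_exact_recovery_without_noise(self, rng):
        X = rng.uniform(0, 2, size=(200, 6))
        w_true = rng.normal(size=6)
        model = fit_linear(X, X @ w_true + 1.5)
        np.testing.assert_allclose(model.weights, w_true, atol=1e-8)
        assert model.intercept == pytest.approx(1.5, abs=1e-8)

    def test_zero_penalty_matches_unpenalized(self, rng):
        X = rng.uniform(0, 2, size=(150, 4))
        y = X @ np.array([0.5, -1.0, 2.0, 0.1]) + rng.normal(scale=0.1, size=150)
        plain = fit_linear(X, y)
        gridded = fit_linear(X[:100], y[:100], elastic_net=([0.0], [0.0]),
                             X_val=X[100:], y_val=y[100:])
        ref = fit_linear(X[:100], y[:100])
        np.testing.assert_allclose(gridded.weights, ref.weights, atol=1e-6)
        assert plain.lambda1 == 0.0

    def test_indicator_interaction_not_linearly_representable(self, rng):
        g = rng.integers(0, 3, size=(4000, 2)).astype(float)
        y = ((g[:, 0] == 1) & (g[:, 1] == 1)).astype(float) * 3.0
        model = fit_linear(g[:3000], y[:3000])
        lin_mse = np.mean((model.predict(g[3000:]) - y[3000:]) ** 2)
        assert lin_mse > 0.05

    def test_rank_deficiency_warns(self, rng):
        X = np.repeat(rng.uniform(0, 2, size=(80, 1)), 3, axis=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_linear(X, X[:, 0])

    def test_elastic_grid_selects_by_validation(self, rng):
        X = rng.uniform(0, 2, size=(300, 5))
        y = X @ np.array([1.0, 0, 0, 0, 0]) + rng.normal(scale=0.05, size=300)
        model = fit_linear(X[:200], y[:200], elastic_net=([0.0, 0.1, 10.0], [0.0, 0.1]),
                           X_val=X[200:], y_val=y[200:])
        mse = np.mean((model.predict(X[200:]) - y[200:]) ** 2)
        assert mse < 0.01


class TestAeMlp:
    def test_zero_mlp_with_bias_outputs_constant(self, rng):
        ae = build_autoencoder(3, 3, seed=0)
        mlp = build_mlp(3, seed=0)
        for w in mlp.weights:
            w[:] = 0.0
        for b in mlp.biases:
            b[:] = 0.0
        mlp.biases[-1][:] = 4.2
        out = predict_ae_mlp(ae, mlp, rng.uniform(0, 2, size=(10, 3)))
        np.testing.assert_allclose(out, 4.2)

    def test_snp_order_mismatch_rejected(self):
        ae = build_autoencoder(2, 3, output_names=["a", "b", "c"])
        mlp = build_mlp(3, input_snp_ids=["a", "c", "b"])
        with pytest.raises(ValueError, match="order"):
            predict_ae_mlp(ae, mlp, np.zeros((1, 2)))

    def test_width_mismatch_rejected(self):
        ae = build_autoencoder(2, 3)
        mlp = build_mlp(4)
        with pytest.raises(ValueError, match="width"):
            predict_ae_mlp(ae, mlp, np.zeros((1, 2)))
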