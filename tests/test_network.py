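"""BiLSTM network: forward semantics, training loop, gradient correctness."""

import numpy as np
import pytest

from wavelstm import (
    GeneratorConfig,
    LSTMParameters,
    NetworkModel,
    NetworkTopology,
    TrainingConfig,
    bilstm_forward,
    generate_feature_dataset,
    gradient_check,
    load_model,
    network_forward,
    predict,
    reduce_features,
    save_model,
    train,
)


def tiny_model(rng, hidden=3, fc=4, n_classes=2, dropout=0.0):
    return NetworkModel.initialize(
        NetworkTopology(hidden_units=hidden, fc_hidden=fc, dropout_rate=dropout),
        n_classes, rng,
    )


def zero_model(hidden=3, n_classes=2):
    z = np.zeros((hidden, hidden + 1))
    zb = np.zeros(hidden)
    p = LSTMParameters(W_f=z.copy(), W_i=z.copy(), W_c=z.copy(), W_o=z.copy(),
                       b_f=zb.copy(), b_i=zb.copy(), b_c=zb.copy(), b_o=zb.copy())
    q = LSTMParameters(W_f=z.copy(), W_i=z.copy(), W_c=z.copy(), W_o=z.copy(),
                       b_f=zb.copy(), b_i=zb.copy(), b_c=zb.copy(), b_o=zb.copy())
    return NetworkModel(
        forward_params=p, backward_params=q,
        fc1_W=np.zeros((4, 2 * hidden)), fc1_b=np.zeros(4),
        fc2_W=np.zeros((n_classes, 4)), fc2_b=np.zeros(n_classes),
        n_classes=n_classes, dropout_rate=0.0,
    )


class TestForward:
    def test_bilstm_output_length_is_twice_hidden(self, rng):
        model = tiny_model(rng, hidden=7)
        out = bilstm_forward(rng.normal(size=30), model)
        assert out.shape == (14,)

    def test_zero_parameters_give_zero_representation(self, rng):
        out = bilstm_forward(rng.normal(size=20), zero_model())
        np.testing.assert_array_equal(out, 0.0)

    def test_palindrome_with_tied_directions_gives_equal_halves(self, rng):
        model = tiny_model(rng, hidden=5)
        model.backward_params = model.forward_params
        seq = rng.normal(size=11)
        pal = np.concatenate([seq, seq[::-1]])
        out = bilstm_forward(pal, model)
        np.testing.assert_allclose(out[:5], out[5:], atol=1e-12)

    def test_reversal_swaps_direction_roles(self, rng):
        model = tiny_model(rng, hidden=4)
        swapped = NetworkModel(
            forward_params=model.backward_params,
            backward_params=model.forward_params,
            fc1_W=model.fc1_W, fc1_b=model.fc1_b,
            fc2_W=model.fc2_W, fc2_b=model.fc2_b,
            n_classes=model.n_classes, dropout_rate=model.dropout_rate,
        )
        seq = rng.normal(size=17)
        a = bilstm_forward(seq, model)
        b = bilstm_forward(seq[::-1], swapped)
        np.testing.assert_allclose(a[:4], b[4:], atol=1e-12)
        np.testing.assert_allclose(a[4:], b[:4], atol=1e-12)

    def test_probabilities_normalized(self, rng):
        model = tiny_model(rng, n_classes=3)
        probs = network_forward(rng.normal(size=25), model)
        assert probs.shape == (3,)
        assert (probs >= 0).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_inference_deterministic_despite_dropout_rate(self, rng):
        model = tiny_model(rng, dropout=0.5)
        x = rng.normal(size=16)
        np.testing.assert_array_equal(network_forward(x, model),
                                      network_forward(x, model))

    def test_symmetric_logits_give_uniform_probabilities(self, rng):
        model = tiny_model(rng)
        model.fc2_W[1] = model.fc2_W[0]
        model.fc2_b[:] = 0.0
        probs = network_forward(rng.normal(size=12), model)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)

    def test_non_finite_input_rejected(self, rng):
        model = tiny_model(rng)
        with pytest.raises(ValueError):
            network_forward(np.array([1.0, np.nan, 0.0]), model)


class TestGradients:
    def test_finite_difference_check(self, rng):
        for trial in range(3):
            model = tiny_model(rng, hidden=3, fc=3)
            x = rng.normal(size=8)
            assert gradient_check(model, x, trial % 2) < 1e-5

    def test_oracle_detects_a_corrupted_gate_equation(self, rng):
        """A deliberately wrong memory update must trip the comparison."""
        import wavelstm.lstm as lstm_mod
        model = tiny_model(rng, hidden=3, fc=3)
        model.fc1_b += 0.5  # keep the ReLU layer active so gradients flow
        x = rng.normal(size=8)
        baseline = gradient_check(model, x, 1)
        orig = lstm_mod.lstm_sequence_backward

        def corrupted(dh_final, cache, Wr, truncation_rtol=1e-10):
            dWr, dWx, db = orig(dh_final, cache, Wr, truncation_rtol)
            return dWr * 1.05, dWx, db  # mis-scaled recurrent gradient

        lstm_mod_backward = lstm_mod.lstm_sequence_backward
        try:
            import wavelstm.network as net_mod
            net_mod.lstm_sequence_backward = corrupted
            corrupted_err = gradient_check(model, x, 1)
        finally:
            net_mod.lstm_sequence_backward = lstm_mod_backward
        assert corrupted_err > 10 * max(baseline, 1e-8)


@pytest.fixture(scope="module")
def separable():
    cfg = GeneratorConfig(
        n_per_class=30, n_classes=2, dim=64, sparsity=0.8,
        spike_rate_per_class=(8.0, 2.0), spike_scale=12.0,
        noise_sd=0.02, seed=42,
    )
    data = generate_feature_dataset(cfg)
    return reduce_features(data.features, "dwt"), data.labels


class TestTraining:
    def test_zero_learning_rate_is_a_no_op(self, separable):
        X, y = separable
        config = TrainingConfig(epochs=2, learning_rate=0.0, seed=5,
                                precision="double")
        model, log = train(X, y, config=config,
                           topology=NetworkTopology(dropout_rate=0.0))
        fresh = NetworkModel.initialize(
            NetworkTopology(dropout_rate=0.0), 2, np.random.default_rng(5)
        )
        np.testing.assert_array_equal(model.fc1_W, fresh.fc1_W)
        np.testing.assert_array_equal(model.forward_params.W_c,
                                      fresh.forward_params.W_c)
        # individual minibatch losses vary with the shuffle, but the epoch
        # mean is the fixed whole-sample loss when parameters never move
        assert abs(log.epoch_mean_loss(0) - log.epoch_mean_loss(1)) < 1e-12

    def test_same_seed_reproduces_loss_trace(self, separable):
        X, y = separable
        config = TrainingConfig(epochs=2, seed=9, learning_rate=0.003)
        _, log1 = train(X, y, config=config)
        _, log2 = train(X, y, config=config)
        assert log1.loss == log2.loss

    def test_separable_set_reaches_full_training_accuracy(self, separable):
        """Pinned-seed reference run: strong spikes, 50 epochs, dim 64."""
        X, y = separable
        model, log = train(
            X, y,
            config=TrainingConfig(epochs=50, seed=13, learning_rate=0.003),
            topology=NetworkTopology(dropout_rate=0.0),
        )
        pred, _ = predict(model, X)
        assert (pred == y).mean() == 1.0
        assert log.epoch_mean_loss(49) < log.epoch_mean_loss(0)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 16))
        with pytest.raises(ValueError):
            train(X, np.zeros(10, dtype=int), config=TrainingConfig(epochs=1))

    def test_non_finite_features_rejected(self):
        X = np.full((6, 8), np.nan)
        with pytest.raises(ValueError):
            train(X, np.array([0, 1] * 3), config=TrainingConfig(epochs=1))


class TestPredict:
    def test_tie_breaks_to_lower_class_index(self, rng):
        model = tiny_model(rng)
        model.fc2_W[1] = model.fc2_W[0]
        model.fc2_b[:] = 0.0
        labels, probs = predict(model, rng.normal(size=(3, 10)))
        assert (labels == 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_row_order_invariance(self, rng):
        model = tiny_model(rng)
        X = rng.normal(size=(6, 12))
        labels, probs = predict(model, X)
        labels_r, probs_r = predict(model, X[::-1])
        np.testing.assert_array_equal(labels_r, labels[::-1])
        np.testing.assert_allclose(probs_r, probs[::-1], atol=1e-12)

    def test_width_mismatch_after_training_rejected(self, rng):
        X = rng.normal(size=(12, 16))
        y = np.array([0, 1] * 6)
        model, _ = train(X, y, config=TrainingConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(2, 20)))


def test_model_serialization_roundtrip(tmp_path, rng):
    model = tiny_model(rng, hidden=4, fc=5, n_classes=3)
    save_model(model, tmp_path / "m")
    loaded = load_model(tmp_path / "m")
    x = rng.normal(size=9)
    np.testing.assert_allclose(network_forward(x, loaded),
                               network_forward(x, model), atol=1e-15)
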