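"""BiLSTM-attention network: shapes, equations, gradients, training loop."""

import numpy as np
import pytest

from apindel.labels import LabelError
from apindel.network import (
    ApindelNetwork,
    IndelOutcomePredictor,
    NetworkConfig,
    attention_scores,
    train_network,
)


def _tiny_net(**kw):
    defaults = dict(
        input_dim=4, seq_len=3, n_classes=5, units=3, attention_T=2,
        mlp_hidden=4, dropout_p=0.0, l1_lambda=1e-3, activation="relu", seed=0,
    )
    defaults.update(kw)
    return ApindelNetwork(**defaults)


class TestFeatures:
    def test_canonical_shape_full_size(self, rng):
        net = ApindelNetwork(input_dim=150, seq_len=59, n_classes=557, units=50)
        H = net.features(rng.normal(size=(2, 59, 150)))
        assert H.shape == (2, 59, 100)

    def test_zero_input_zero_bias_gives_zero_features(self):
        net = _tiny_net()
        net.params["bf"][:] = 0.0
        net.params["bb"][:] = 0.0
        H = net.features(np.zeros((2, 3, 4)))
        assert np.allclose(H, 0.0)

    def test_direction_symmetry_under_reversal(self, rng):
        """Reversing the input swaps the forward/backward halves when the
        direction parameters are swapped too."""
        net = _tiny_net()
        X = rng.normal(size=(2, 3, 4))
        H = net.features(X)
        swapped = _tiny_net()
        for a, b in (("Wf", "Wb"), ("Rf", "Rb"), ("bf", "bb")):
            swapped.params[a] = net.params[b].copy()
            swapped.params[b] = net.params[a].copy()
        H_rev = swapped.features(X[:, ::-1])
        U = net.units
        assert np.allclose(H[:, :, :U], H_rev[:, ::-1, U:])
        assert np.allclose(H[:, :, U:], H_rev[:, ::-1, :U])

    def test_non_finite_input_rejected(self):
        net = _tiny_net()
        X = np.zeros((1, 3, 4))
        X[0, 0, 0] = np.nan
        with pytest.raises(LabelError):
            net.features(X)


class TestAttention:
    def test_identical_rows_uniform(self, rng):
        H = np.tile(rng.normal(size=(1, 1, 6)), (1, 4, 1))
        a = attention_scores(H, rng.normal(size=(2, 6)), rng.normal(size=2))
        assert np.allclose(a, 0.25)

    def test_hand_evaluation_two_positions(self):
        """Direct evaluation of the softmax(tanh) attention equations."""
        H = np.array([[[0.0], [10.0]]])
        a = attention_scores(H, np.array([[1.0]]), np.array([1.0]))
        z = np.tanh(10.0) - np.tanh(0.0)
        expect0 = 1.0 / (1.0 + np.exp(z))
        assert a[0, 0] == pytest.approx(expect0)
        assert a.sum() == pytest.approx(1.0, abs=1e-6)

    def test_shift_invariance(self, rng):
        H = rng.normal(size=(3, 5, 4))
        W1, w2 = rng.normal(size=(2, 4)), rng.normal(size=2)
        a1 = attention_scores(H, W1, w2)
        # adding a constant to every score leaves the softmax unchanged:
        # equivalent to scaling all exp terms by the same factor
        u = np.tanh(H @ W1.T) @ w2
        e = np.exp(u + 7.3)
        a2 = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(a1, a2)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(LabelError):
            attention_scores(rng.normal(size=(1, 3, 4)), rng.normal(size=(2, 5)), rng.normal(size=2))


class TestGradients:
    @pytest.mark.parametrize("activation", ["relu", "tanh"])
    def test_backprop_matches_finite_differences(self, activation):
        rng = np.random.default_rng(1)
        net = _tiny_net(activation=activation)
        X = rng.normal(size=(3, 3, 4))
        Y = rng.dirichlet(np.ones(5), size=3)

        def loss_only():
            rm, rv = net.running_mean.copy(), net.running_var.copy()
            val, _, _ = net.loss_and_grads(X, Y)
            net.running_mean, net.running_var = rm, rv
            return val

        rm, rv = net.running_mean.copy(), net.running_var.copy()
        _, grads, _ = net.loss_and_grads(X, Y)
        net.running_mean, net.running_var = rm, rv
        eps = 1e-6
        for key, p in net.params.items():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                k = it.multi_index
                p[k] += eps
                Jp = loss_only()
                p[k] -= 2 * eps
                Jm = loss_only()
                p[k] += eps
                num[k] = (Jp - Jm) / (2 * eps)
            denom = np.maximum(np.abs(num), np.abs(grads[key])) + 1e-8
            assert (np.abs(grads[key] - num) / denom).max() < 1e-4, key


class TestPrediction:
    def test_output_on_simplex(self, rng):
        net = _tiny_net()
        P = net.predict_proba(rng.normal(size=(7, 3, 4)))
        assert P.shape == (7, 5)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert (P >= 0).all()

    def test_repeated_calls_bit_stable(self, rng):
        net = _tiny_net()
        X = rng.normal(size=(4, 3, 4))
        assert np.array_equal(net.predict_proba(X), net.predict_proba(X))

    def test_zero_final_layer_gives_uniform(self, rng):
        net = _tiny_net()
        net.params["Wo"][:] = 0.0
        net.params["bo"][:] = 0.0
        P = net.predict_proba(rng.normal(size=(2, 3, 4)))
        assert np.allclose(P, 1.0 / 5)


class TestTraining:
    def _toy_data(self, rng, n=10):
        X = rng.normal(size=(n, 3, 4))
        Y = rng.dirichlet(np.full(5, 0.1), size=n)  # low-entropy soft labels
        return X, Y

    def test_overfits_toy_set(self, rng):
        X, Y = self._toy_data(rng)
        net = _tiny_net(l1_lambda=0.0, mlp_hidden=16, units=6, attention_T=4)
        cfg = NetworkConfig(
            learning_rate=1e-2, max_epochs=120, batch_size=5, dropout_p=0.0,
            lr_patience=1000, stop_patience=1000, init_output_bias=False, seed=0,
        )
        h = train_network(net, X, Y, X, Y, cfg)
        assert h.train_loss.iloc[-1] < 0.5 * h.train_loss.iloc[0]

    def test_seeded_determinism(self, rng):
        X, Y = self._toy_data(rng, n=12)
        cfg = NetworkConfig(learning_rate=1e-3, max_epochs=4, batch_size=4, seed=5)
        runs = []
        for _ in range(2):
            net = _tiny_net(dropout_p=0.5, seed=5)
            h = train_network(net, X[:8], Y[:8], X[8:], Y[8:], cfg)
            runs.append(h)
        assert runs[0]["val_mse"].tolist() == runs[1]["val_mse"].tolist()
        assert runs[0]["train_loss"].tolist() == runs[1]["train_loss"].tolist()

    def test_lr_schedule_contract(self, rng):
        """The learning-rate trace never increases and every decrease is
        exactly the configured factor."""
        X, Y = self._toy_data(rng, n=12)
        cfg = NetworkConfig(
            learning_rate=1e-3, max_epochs=15, batch_size=4,
            lr_patience=1, stop_patience=100, seed=0,
        )
        net = _tiny_net()
        h = train_network(net, X[:8], Y[:8], X[8:], Y[8:], cfg)
        lrs = h["lr"].tolist()
        for prev, cur in zip(lrs, lrs[1:]):
            assert cur <= prev
            if cur < prev:
                assert cur / prev == pytest.approx(0.2)

    def test_empty_split_errors(self, rng):
        X, Y = self._toy_data(rng)
        with pytest.raises(LabelError):
            train_network(_tiny_net(), X[:0], Y[:0], X, Y, NetworkConfig())

    def test_best_weights_restored(self, rng):
        X, Y = self._toy_data(rng, n=12)
        cfg = NetworkConfig(learning_rate=5e-2, max_epochs=12, batch_size=4,
                            lr_patience=100, stop_patience=100, seed=0)
        net = _tiny_net()
        h = train_network(net, X[:8], Y[:8], X[8:], Y[8:], cfg)
        final_mse = float(np.mean((net.predict_proba(X[8:]) - Y[8:]) ** 2))
        assert final_mse == pytest.approx(h["val_mse"].min(), rel=1e-9)


class TestEstimator:
    def test_fit_predict_on_synthetic_records(self, small_dataset):
        from apindel.embedding import GloveEmbedder

        recs = small_dataset[:60]
        X = [r.sequence for r in recs]
        y = np.stack([r.distribution for r in recs])
        model = IndelOutcomePredictor(
            embedder=GloveEmbedder(dim=8, max_iter=30, random_state=1),
            units=4, attention_T=4, mlp_hidden=8, max_epochs=2,
            batch_size=16, random_state=1,
        )
        model.fit(X, y)
        P = model.predict(X[:5])
        assert P.shape == (5, 557)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        a = model.attention(X[:3])
        assert a.shape == (3, 59)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-6)
        prof = model.attention_profile(X[:3])
        assert prof.shape == (59,)
        assert prof.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(prof, a.mean(axis=0))

    def test_wrong_length_sequence_rejected(self, small_dataset):
        model = IndelOutcomePredictor()
        model.embedder_ = None
        with pytest.raises(LabelError, match="60"):
            model._embed(["ACGT" * 10])

    def test_single_record_profile_is_its_vector(self, small_dataset):
        from apindel.embedding import GloveEmbedder

        recs = small_dataset[:40]
        X = [r.sequence for r in recs]
        y = np.stack([r.distribution for r in recs])
        model = IndelOutcomePredictor(
            embedder=GloveEmbedder(dim=8, max_iter=20, random_state=2),
            units=4, attention_T=4, mlp_hidden=8, max_epochs=1,
            batch_size=16, random_state=2,
        )
        model.fit(X, y)
        assert np.allclose(model.attention_profile(X[:1]), model.attention(X[:1])[0])
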