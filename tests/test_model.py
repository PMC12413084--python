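"""The score regressor: prediction, training, and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zipscore.alphabet import DEFAULT_ALPHABET, digits_to_onehot, seqs_to_digits
from zipscore.model import (
    DivergenceError,
    ModelFormatError,
    ScoredSegment,
    ScoreModel,
    TrainingConfig,
    _Dense,
    _ReLU,
    classify_zipper,
    confusion_metrics,
    evaluate_error_bands,
    predict_score,
    split_sizes,
    train_model,
)
from zipscore.synthetic import make_ground_truth, sample_dataset


def _fc_model(W1, b1, W2, b2, alphabet=DEFAULT_ALPHABET):
    rng = np.random.default_rng(0)
    d1 = _Dense(W1.shape[0], W1.shape[1], rng)
    d2 = _Dense(W1.shape[1], 1, rng)
    d1.W[...] = W1
    d1.b[...] = b1
    d2.W[:, 0] = W2
    d2.b[0] = b2
    return ScoreModel(layers=[d1, _ReLU(), d2], alphabet=alphabet)


class TestPredict:
    def test_zero_weight_network_outputs_bias(self):
        m = _fc_model(np.zeros((120, 120)), np.zeros(120), np.zeros(120), -19.0)
        for seq in ("AAAAAA", "NNQQNY", "YYYYYY"):
            assert predict_score(m, seq) == pytest.approx(-19.0)

    def test_single_hidden_unit_arithmetic(self):
        # one active unit summing all six one-hot entries: 6 - 5 = 1, times 2
        W1 = np.zeros((120, 120))
        W1[:, 0] = 1.0
        b1 = np.zeros(120)
        b1[0] = -5.0
        W2 = np.zeros(120)
        W2[0] = 2.0
        m = _fc_model(W1, b1, W2, 0.0)
        assert predict_score(m, "MKLVFW") == pytest.approx(2.0)

    def test_relu_clamps_negative_preactivation(self):
        W1 = np.zeros((120, 120))
        W1[:, 0] = 1.0
        b1 = np.zeros(120)
        b1[0] = -7.0  # pre-activation 6 - 7 = -1 -> ReLU 0
        W2 = np.zeros(120)
        W2[0] = 2.0
        m = _fc_model(W1, b1, W2, 0.0)
        assert predict_score(m, "MKLVFW") == pytest.approx(0.0)

    def test_batch_equals_elementwise(self):
        gt = make_ground_truth(seed=2)
        data = sample_dataset(gt, 2000, seed=2)
        df = pd.concat(data.values(), ignore_index=True)
        res = train_model(df, TrainingConfig(epochs=3, seed=2))
        seqs = df["sequence"].tolist()[:50]
        batch = res.model.predict(seqs)
        singles = np.array([predict_score(res.model, s) for s in seqs])
        assert np.array_equal(batch, singles)
        # permutation consistency
        perm = np.random.default_rng(0).permutation(len(seqs))
        shuffled = res.model.predict([seqs[i] for i in perm])
        assert np.array_equal(shuffled, batch[perm])

    def test_shape_mismatch_raises_model_format_error(self):
        m = _fc_model(np.zeros((120, 120)), np.zeros(120), np.zeros(120), 0.0)
        with pytest.raises(ModelFormatError):
            m.predict_onehot(np.zeros((4, 80), dtype=np.float32))

    def test_forward_pass_matches_sklearn_mlp(self):
        """Independent oracle: same weights loaded into sklearn's MLPRegressor."""
        from sklearn.neural_network import MLPRegressor

        rng = np.random.default_rng(7)
        W1 = rng.normal(size=(120, 120))
        b1 = rng.normal(size=120)
        W2 = rng.normal(size=120)
        b2 = 0.73
        mine = _fc_model(W1, b1, W2, b2)
        ref = MLPRegressor(hidden_layer_sizes=(120,), activation="relu",
                           max_iter=1)
        X = digits_to_onehot(seqs_to_digits(
            ["NNQQNY", "AAAAAA", "MKLVFW", "YYYYYY"]))
        y = np.zeros(4)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref.fit(X, y)
        ref.coefs_ = [W1, W2.reshape(-1, 1)]
        ref.intercepts_ = [b1, np.array([b2])]
        assert np.allclose(mine.predict_onehot(X), ref.predict(X), atol=1e-4)


class TestTraining:
    def test_seeded_determinism(self):
        gt = make_ground_truth(seed=4)
        df = pd.concat(sample_dataset(gt, 3000, seed=4).values(),
                       ignore_index=True)
        cfg = TrainingConfig(epochs=5, seed=7)
        r1 = train_model(df, cfg)
        r2 = train_model(df, cfg)
        pd.testing.assert_frame_equal(r1.history, r2.history)
        for l1, l2 in zip(r1.model.layers, r2.model.layers):
            for (p1, _), (p2, _) in zip(l1.params(), l2.params()):
                assert np.array_equal(p1, p2)

    def test_constant_dataset_interpolated(self):
        data = [ScoredSegment("NNQQNY", -27.0)] * 200
        cfg = TrainingConfig(epochs=200, seed=1, batch_size=32,
                             split_fractions=(0.8, 0.1, 0.1))
        res = train_model(data, cfg)
        assert res.history["train_mse"].iloc[-1] < 1e-3
        assert predict_score(res.model, "NNQQNY") == pytest.approx(-27.0, abs=0.05)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TrainingConfig(epochs=1))

    def test_proline_exclusion_filters_corpus(self):
        data = [ScoredSegment("PPPPPP", 100.0), ScoredSegment("AAAAAA", -20.0)] * 50
        res = train_model(data, TrainingConfig(epochs=1, seed=0))
        total = sum(len(s) for s, _ in res.splits.values())
        assert total == 50  # proline half dropped before splitting
        res2 = train_model(data, TrainingConfig(epochs=1, seed=0,
                                                exclude_proline=False))
        assert sum(len(s) for s, _ in res2.splits.values()) == 100

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergent_learning_rate_raises(self):
        gt = make_ground_truth(seed=4)
        df = pd.concat(sample_dataset(gt, 1000, seed=4).values(),
                       ignore_index=True)
        with pytest.raises(DivergenceError):
            train_model(df, TrainingConfig(epochs=50, seed=0,
                                           learning_rate=1e12))

    def test_reported_mse_matches_independent_loop(self):
        """Validation MSE must equal a per-sample squared-residual average."""
        gt = make_ground_truth(seed=9)
        df = pd.concat(sample_dataset(gt, 2000, seed=9).values(),
                       ignore_index=True)
        res = train_model(df, TrainingConfig(epochs=3, seed=9))
        seqs, scores = res.splits["validation"]
        sse = 0.0
        for s, t in zip(seqs, scores):
            sse += (predict_score(res.model, s) - t) ** 2
        assert res.history["val_mse"].iloc[-1] == pytest.approx(
            sse / len(seqs), rel=1e-5)

    def test_split_sizes_floor_with_remainder_to_train(self):
        assert split_sizes(1000, (0.8, 0.15, 0.05)) == (800, 150, 50)
        assert split_sizes(7, (0.791, 0.177, 0.032)) == (6, 1, 0)
        assert sum(split_sizes(12345, (0.791, 0.177, 0.032))) == 12345

    def test_save_load_round_trip_bit_exact(self, tmp_path):
        gt = make_ground_truth(seed=4)
        df = pd.concat(sample_dataset(gt, 1000, seed=4).values(),
                       ignore_index=True)
        res = train_model(df, TrainingConfig(epochs=2, seed=4))
        path = tmp_path / "model.npz"
        res.model.save(path)
        loaded = ScoreModel.load(path)
        seqs = df["sequence"].tolist()[:20]
        assert np.array_equal(loaded.predict(seqs), res.model.predict(seqs))
        assert loaded.metadata == res.model.metadata
        assert loaded.alphabet == res.model.alphabet

    @pytest.mark.parametrize("variant", ["fc_expanded", "fc_extra_layer", "conv1d"])
    def test_architecture_variants_reach_comparable_error(self, variant):
        """Alternative architectures land within 2x of the reference net."""
        gt = make_ground_truth(seed=13)
        df = pd.concat(sample_dataset(gt, 20_000, seed=13).values(),
                       ignore_index=True)
        base = train_model(df, TrainingConfig(epochs=40, seed=13))
        other = train_model(df, TrainingConfig(epochs=40, seed=13,
                                               architecture_variant=variant))
        mse_base = base.holdout_mse()
        mse_other = other.holdout_mse()
        assert mse_other <= max(2.0 * mse_base, 0.05)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Finite-difference oracle for the backward pass of every layer."""
        rng = np.random.default_rng(3)
        from zipscore.model import _build_layers

        for variant in ("fc120", "conv1d"):
            layers = _build_layers(variant, DEFAULT_ALPHABET,
                                   np.random.default_rng(0), None, 4)
            for layer in layers:  # float64 so the finite difference is clean
                if hasattr(layer, "W"):
                    layer.W = layer.W.astype(np.float64)
                    layer.b = layer.b.astype(np.float64)
                    layer.dW = np.zeros_like(layer.W)
                    layer.db = np.zeros_like(layer.b)
            x = digits_to_onehot(seqs_to_digits(["NNQQNY", "MKLVFW"])) \
                .astype(np.float64)
            y = np.array([-25.0, -10.0])

            def loss():
                out = x.copy()
                for layer in layers:
                    out = layer.forward(out)
                return float(np.mean((out[:, 0] - y) ** 2))

            base = loss()
            out = x.copy()
            for layer in layers:
                out = layer.forward(out)
            g = (2.0 / len(y)) * (out[:, 0] - y)
            grad = g[:, None]
            for layer in reversed(layers):
                grad = layer.backward(grad)
            for layer in layers:
                for p, dp in layer.params():
                    flat = p.reshape(-1)
                    for k in rng.choice(flat.size, size=min(3, flat.size),
                                        replace=False):
                        eps = 1e-6
                        old = flat[k]
                        flat[k] = old + eps
                        up = loss()
                        flat[k] = old - eps
                        down = loss()
                        flat[k] = old
                        numeric = (up - down) / (2 * eps)
                        assert dp.reshape(-1)[k] == pytest.approx(
                            numeric, rel=1e-3, abs=1e-6)


class TestEvaluation:
    def test_error_bands_direct_count(self):
        out = evaluate_error_bands([0, 0.4, 1.2], [0, 0, 0], [0.5, 1.0])
        assert out == pytest.approx([2 / 3, 2 / 3])

    def test_error_bands_identity_and_boundary(self):
        assert evaluate_error_bands([1, 2], [1, 2], [0.5, 1.0]) == pytest.approx([1, 1])
        assert evaluate_error_bands([0.5], [0.0], [0.5])[0] == 1.0  # inclusive

    def test_error_bands_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_error_bands([1, 2], [1], [0.5])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    def test_error_bands_monotone_in_band_width(self, errs):
        pred = np.array(errs)
        truth = np.zeros_like(pred)
        bands = [0.1, 0.5, 1.0, 2.0, 10.0]
        fracs = evaluate_error_bands(pred, truth, bands)
        assert (np.diff(fracs) >= 0).all()

    @pytest.mark.parametrize("score,expected", [
        (-23.1, True), (-22.9, False), (-23.0, True),
    ])
    def test_zipper_threshold_boundary(self, score, expected):
        assert classify_zipper(score) is expected

    def test_classify_rejects_nan(self):
        with pytest.raises(ValueError):
            classify_zipper(float("nan"))

    def test_confusion_metrics_formulas(self):
        m = confusion_metrics(tp=926, tn=992, fp=8, fn=74)
        assert m["sensitivity"] == pytest.approx(0.926)
        assert m["specificity"] == pytest.approx(0.992)
        assert m["accuracy"] == pytest.approx(0.959)

    def test_confusion_metrics_edge_cases(self):
        perfect = confusion_metrics(tp=1, tn=1, fp=0, fn=0)
        assert all(v == 1.0 for v in perfect.values())
        empty_pos = confusion_metrics(tp=0, tn=5, fp=1, fn=0)
        assert empty_pos["sensitivity"] is None
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)
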