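"""LSTM selection, the combined loss, training and prediction contracts."""

import numpy as np
import pytest

from multispace import (
    SelectorConfig,
    classify,
    combined_loss,
    generate_feature_fixture,
    lstm_select,
    predict_patches,
    select_features,
    softmax,
    to_sequence,
    train_selector,
)
from multispace.selector import SelectedFeatures, _init_lstm, _lstm_backward, _lstm_forward

from .oracles import lstm_oracle


class TestToSequence:
    def test_row_major_reshape(self):
        cfg = SelectorConfig()
        v = np.arange(2048.0)
        seq = to_sequence(v, cfg)
        assert seq.shape == (64, 32)
        assert seq[0, 31] == v[31]
        assert np.array_equal(seq.reshape(-1), v)

    def test_degenerate_single_column(self):
        cfg = SelectorConfig(seq_len=2048, step_dim=1)
        assert to_sequence(np.arange(2048.0), cfg).shape == (2048, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            to_sequence(np.zeros(100), SelectorConfig())


class TestLstmSelect:
    def test_output_is_32_dim_final_state(self, rng):
        params = _init_lstm(rng, 32, 32)
        out = lstm_select(rng.normal(size=(64, 32)), params)
        assert out.shape == (32,)

    def test_matches_step_by_step_gate_oracle(self, rng):
        # Random 4x3 sequences through a small (H=5) LSTM with fixed weights.
        params = _init_lstm(rng, 3, 5)
        for _ in range(5):
            seq = rng.normal(size=(4, 3))
            np.testing.assert_allclose(
                lstm_select(seq, params), lstm_oracle(params, seq), atol=1e-5
            )

    def test_truncation_changes_output(self, rng):
        params = _init_lstm(rng, 3, 5)
        seq = rng.normal(size=(6, 3))
        full = lstm_select(seq, params)
        truncated = lstm_select(seq[:3], params)
        assert not np.allclose(full, truncated)

    def test_deterministic_and_validates_input(self, rng):
        params = _init_lstm(rng, 32, 32)
        seq = rng.normal(size=(64, 32))
        assert np.array_equal(lstm_select(seq, params), lstm_select(seq, params))
        with pytest.raises(ValueError):
            lstm_select(rng.normal(size=(64, 16)), params)
        with pytest.raises(ValueError):
            lstm_select(seq, {})

    def test_bptt_gradients_match_finite_differences(self, rng):
        # Scalar loss sum(h_T); central differences on every parameter of a
        # tiny LSTM must match the analytic backward pass.
        params = _init_lstm(rng, 3, 4)
        seq = rng.normal(size=(2, 5, 3))
        h, cache = _lstm_forward(params, seq)
        grads, _ = _lstm_backward(params, cache, np.ones_like(h))
        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            for idx in rng.choice(flat.size, size=4, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = _lstm_forward(params, seq)[0].sum()
                flat[idx] = orig - eps
                down = _lstm_forward(params, seq)[0].sum()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(numeric, abs=1e-5)


class TestCombinedLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.array([0.0, 1.0, 0.0])
        assert combined_loss(y, y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_both_streams_is_twice_ln3(self):
        u = np.full(3, 1 / 3)
        y = np.array([1.0, 0.0, 0.0])
        assert combined_loss(u, u, y) == pytest.approx(2 * np.log(3), abs=1e-9)

    def test_one_stream_uniform_is_ln3(self):
        y = np.array([0.0, 0.0, 1.0])
        u = np.full(3, 1 / 3)
        assert combined_loss(y, u, y) == pytest.approx(np.log(3), abs=1e-9)

    def test_nonnegative_on_random_simplexes(self, rng):
        for _ in range(20):
            a = rng.dirichlet(np.ones(3))
            b = rng.dirichlet(np.ones(3))
            y = np.eye(3)[rng.integers(3)]
            assert combined_loss(a, b, y) >= 0.0

    def test_zero_probability_guarded(self):
        y = np.array([1.0, 0.0, 0.0])
        a = np.array([0.0, 1.0, 0.0])
        assert np.isfinite(combined_loss(a, a, y))


class TestClassify:
    def _model(self, zero_heads=False):
        rgb, rec, labels = generate_feature_fixture(n_per_class=2, separation=1.0, seed=0)
        model = train_selector(rgb, rec, labels, SelectorConfig(iterations=1, seed=0))
        if zero_heads:
            for key in ("Wa", "Wb", "Wf"):
                model.heads[key] = np.zeros_like(model.heads[key])
            for key in ("ba", "bb", "bf"):
                model.heads[key] = np.zeros_like(model.heads[key])
        return model

    def test_zero_weights_give_uniform_outputs(self, rng):
        model = self._model(zero_heads=True)
        f = SelectedFeatures(rgb32=rng.normal(size=32), rec32=rng.normal(size=32))
        probs = classify(model, f)
        for v in (probs.a, probs.b, probs.fused):
            np.testing.assert_allclose(v, 1 / 3, atol=1e-12)

    def test_softmax_shift_invariance(self, rng):
        logits = rng.normal(size=(4, 3))
        np.testing.assert_allclose(softmax(logits), softmax(logits + 7.3), atol=1e-12)

    def test_softmax_closed_form(self):
        p = softmax(np.array([1.0, 0.0, 0.0]))
        e = np.e
        np.testing.assert_allclose(p, [e / (e + 2), 1 / (e + 2), 1 / (e + 2)], atol=1e-12)

    def test_outputs_are_simplexes(self, rng):
        model = self._model()
        f = SelectedFeatures(rgb32=rng.normal(size=(5, 32)), rec32=rng.normal(size=(5, 32)))
        probs = classify(model, f)
        for v in (probs.a, probs.b, probs.fused):
            assert np.all(v >= 0)
            np.testing.assert_allclose(v.sum(axis=-1), 1.0, atol=1e-9)


class TestTrainSelector:
    def test_same_seed_identical_weights(self, feature_fixture):
        rgb, rec, labels = feature_fixture
        cfg = SelectorConfig(iterations=2, seed=9)
        m1 = train_selector(rgb[::10], rec[::10], labels[::10], cfg)
        m2 = train_selector(rgb[::10], rec[::10], labels[::10], cfg)
        assert all(np.array_equal(m1.lstm_rgb[k], m2.lstm_rgb[k]) for k in m1.lstm_rgb)
        assert all(np.array_equal(m1.heads[k], m2.heads[k]) for k in m1.heads)
        assert m1.loss_trace == m2.loss_trace

    def test_missing_class_rejected(self, feature_fixture):
        rgb, rec, labels = feature_fixture
        only_class0 = labels == 0
        with pytest.raises(ValueError, match="absent"):
            train_selector(rgb[only_class0], rec[only_class0], labels[only_class0], SelectorConfig(iterations=1))

    def test_separable_features_reach_low_loss_and_high_train_accuracy(self):
        rgb, rec, labels = generate_feature_fixture(n_per_class=30, separation=10.0, seed=2)
        model = train_selector(rgb, rec, labels, SelectorConfig(iterations=10, seed=2))
        assert model.loss_trace[-1] < 0.3
        assert model.loss_trace[-1] < model.loss_trace[0]
        _, pred = predict_patches(model, rgb, rec)
        assert (pred == labels).mean() >= 0.95

    def test_model_save_load_roundtrip(self, tmp_path, feature_fixture):
        rgb, rec, labels = feature_fixture
        model = train_selector(rgb[::10], rec[::10], labels[::10], SelectorConfig(iterations=1, seed=4))
        path = tmp_path / "model.npz"
        model.save(path)
        from multispace import SelectorModel

        loaded = SelectorModel.load(path)
        assert loaded.config == model.config
        probs_a, labels_a = predict_patches(model, rgb[:9], rec[:9])
        probs_b, labels_b = predict_patches(loaded, rgb[:9], rec[:9])
        np.testing.assert_allclose(probs_a.fused, probs_b.fused, atol=1e-12)
        assert np.array_equal(labels_a, labels_b)


class TestPredictPatches:
    def test_argmax_and_tie_rule(self, feature_fixture):
        rgb, rec, labels = feature_fixture
        model = train_selector(rgb[::10], rec[::10], labels[::10], SelectorConfig(iterations=1, seed=4))
        probs, pred = predict_patches(model, rgb[:5], rec[:5])
        assert np.array_equal(pred, np.argmax(np.atleast_2d(probs.fused), axis=-1))
        # Tie-break convention directly on argmax semantics:
        assert np.argmax(np.array([0.5, 0.5, 0.0])) == 0

    def test_batch_equals_per_sample(self, feature_fixture):
        rgb, rec, labels = feature_fixture
        model = train_selector(rgb[::10], rec[::10], labels[::10], SelectorConfig(iterations=1, seed=4))
        _, batch = predict_patches(model, rgb[:4], rec[:4])
        singles = [predict_patches(model, rgb[i], rec[i])[1][0] for i in range(4)]
        assert np.array_equal(batch, singles)

    def test_selected_feature_dimensions(self, feature_fixture):
        rgb, rec, labels = feature_fixture
        model = train_selector(rgb[::10], rec[::10], labels[::10], SelectorConfig(iterations=1, seed=4))
        f = select_features(model, rgb[:3], rec[:3])
        assert f.rgb32.shape == (3, 32)
        assert f.rec32.shape == (3, 32)
        assert f.fused64.shape == (3, 64)
        assert np.array_equal(f.fused64, np.concatenate([f.rgb32, f.rec32], axis=-1))
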