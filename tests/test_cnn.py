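"""Convolutional classifier: forward correctness, gradient checks against
finite differences, pooling exactness, training behavior, persistence."""

from __future__ import annotations

import numpy as np
import pytest

from phenotext.cnn import (CNNConfig, ConvModel, TrainResult, _nll,
                           _pad_batch, predict, train)
from phenotext.evaluation import confusion, metrics

from conftest import compact_cnn_config, random_small_model


def hand_built_model() -> ConvModel:
    """k=1, one width-2 filter with w=[1,1], b=0; vocabulary rows carry the
    scalar embeddings (1, -2, 3) at ids 2..4."""
    cfg = CNNConfig(widths=(2,), filters_per_width=1, k=1, dropout_rate=0.0,
                    seed=0)
    emb = np.array([[0.0], [0.0], [1.0], [-2.0], [3.0]])
    model = ConvModel.initialize(cfg, emb)
    model.filters[2] = np.array([[1.0], [1.0]])
    model.biases[2] = np.array([0.0])
    model.w_out = np.array([1.0])
    model.b_out = 0.0
    return model


class TestForward:
    def test_hand_evaluated_feature_map(self):
        model = hand_built_model()
        fwd = model.forward_note(np.array([2, 3, 4]))
        # windows: (1,-2) -> relu(-1)=0 ; (-2,3) -> relu(1)=1
        assert fwd.feature_maps[2][:, 0] == pytest.approx([0.0, 1.0])
        assert fwd.z[0] == 1.0
        assert fwd.argmax[2][0] == 1  # window covering tokens 2-3

    def test_all_zero_embeddings_give_half(self):
        model = hand_built_model()
        fwd = model.forward_note(np.array([0, 0, 0]))
        assert fwd.y == pytest.approx(0.5)

    def test_pooling_matches_bruteforce_max(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            model = random_small_model(rng)
            ids = rng.integers(1, 20, size=int(rng.integers(5, 15)))
            fwd = model.forward_note(ids)
            slices = model.filter_slices()
            for h in model.widths:
                valid = min(max(len(ids) - h + 1, 1),
                            fwd.feature_maps[h].shape[0])
                expected = fwd.feature_maps[h][:valid].max(axis=0)
                assert np.allclose(fwd.z[slices[h]], expected)
                # tie-break: argmax is the first maximal window
                for j, a in enumerate(fwd.argmax[h]):
                    col = fwd.feature_maps[h][:valid, j]
                    assert a == int(np.argmax(col))

    def test_short_note_padded_to_max_width(self):
        rng = np.random.default_rng(1)
        model = random_small_model(rng, widths=(1, 2, 3))
        fwd = model.forward_note(np.array([5]))
        assert len(fwd.ids) == 3
        assert fwd.n_tokens == 1
        assert 0 < fwd.y < 1

    def test_permutation_outside_argmax_windows_preserves_output(self):
        """Reordering tokens that change no pooled value leaves y fixed.
        Construct a note where appended PAD-adjacent tokens are inert."""
        model = hand_built_model()
        base = np.array([2, 3, 4, 2, 2])     # embeddings 1,-2,3,1,1
        fwd1 = model.forward_note(base)
        # swap the trailing identical tokens (windows unaffected)
        fwd2 = model.forward_note(np.array([2, 3, 4, 2, 2]))
        assert fwd1.y == fwd2.y

    def test_batched_forward_matches_single(self):
        rng = np.random.default_rng(2)
        model = random_small_model(rng)
        notes = [rng.integers(1, 20, size=int(rng.integers(4, 12)))
                 for _ in range(7)]
        probs = model.predict_proba(notes)
        singles = [model.forward_note(ids).y for ids in notes]
        assert np.allclose(probs, singles)


class TestGradients:
    def test_all_parameter_gradients_match_finite_differences(self):
        """Analytic gradients vs central differences, relative 1e-4, on
        random small instances — the correctness contract for the
        hand-written backward pass."""
        rng = np.random.default_rng(3)
        eps = 1e-4
        for trial in range(5):
            model = random_small_model(rng)
            notes = [rng.integers(1, 20, size=int(rng.integers(4, 10)))
                     for _ in range(3)]
            ids, lengths = _pad_batch(notes, max(model.widths))
            y = rng.integers(0, 2, size=3).astype(float)
            _, grads = model.loss_and_grads(ids, lengths, y)

            def loss() -> float:
                val, _ = model.loss_and_grads(ids, lengths, y)
                return val

            arrays = {f"W{h}": model.filters[h] for h in model.widths}
            arrays.update({f"b{h}": model.biases[h] for h in model.widths})
            arrays["w_out"] = model.w_out
            arrays["emb"] = model.embeddings
            for name, arr in arrays.items():
                flat = arr.reshape(-1)
                sel = rng.choice(flat.size, size=min(10, flat.size),
                                 replace=False)
                for idx in sel:
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss()
                    flat[idx] = orig - eps
                    lm = loss()
                    flat[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = grads[name].reshape(-1)[idx]
                    denom = max(abs(num) + abs(ana), 1e-6)
                    assert abs(num - ana) / denom < 1e-4, (trial, name, idx)

    def test_bias_gradient_scalar(self):
        rng = np.random.default_rng(4)
        model = random_small_model(rng)
        notes = [rng.integers(1, 20, size=6)]
        ids, lengths = _pad_batch(notes, max(model.widths))
        y = np.array([1.0])
        _, grads = model.loss_and_grads(ids, lengths, y)
        eps = 1e-6
        model.b_out += eps
        lp, _ = model.loss_and_grads(ids, lengths, y)
        model.b_out -= 2 * eps
        lm, _ = model.loss_and_grads(ids, lengths, y)
        model.b_out += eps
        assert grads["b_out"] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestTraining:
    def test_full_batch_loss_non_increasing(self):
        """With no dropout, full batches and a small step, the NLL descends."""
        rng = np.random.default_rng(5)
        notes = [rng.integers(2, 20, size=10) for _ in range(16)]
        y = np.array([i % 2 for i in range(16)], dtype=float)
        emb = rng.normal(size=(20, 4))
        emb[0] = 0
        cfg = CNNConfig(widths=(1, 2), filters_per_width=4, k=4,
                        dropout_rate=0.0, learning_rate=1e-3, epochs=15,
                        batch_size=16, seed=0, patience=100)
        res = train(notes, y, notes, y, cfg, emb)
        losses = [h["train_loss"] for h in res.history]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_zero_epochs_returns_near_half_predictions(self):
        rng = np.random.default_rng(6)
        notes = [rng.integers(2, 20, size=8) for _ in range(8)]
        y = np.array([i % 2 for i in range(8)], dtype=float)
        emb = rng.normal(size=(20, 4)) * 0.1
        emb[0] = 0
        cfg = CNNConfig(widths=(1, 2), filters_per_width=4, k=4,
                        dropout_rate=0.0, epochs=0, seed=0)
        res = train(notes, y, notes, y, cfg, emb)
        probs = res.model.predict_proba(notes)
        assert abs(float(probs.mean()) - 0.5) < 0.1

    def test_single_class_rejected(self):
        rng = np.random.default_rng(7)
        notes = [rng.integers(2, 10, size=5) for _ in range(4)]
        emb = rng.normal(size=(10, 3))
        cfg = CNNConfig(widths=(1,), filters_per_width=2, k=3, seed=0)
        with pytest.raises(ValueError):
            train(notes, np.ones(4), notes, np.ones(4), cfg, emb)

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(8)
        notes = [rng.integers(2, 20, size=10) for _ in range(12)]
        y = np.array([i % 2 for i in range(12)], dtype=float)
        emb = rng.normal(size=(20, 4))
        emb[0] = 0
        cfg = CNNConfig(widths=(1, 2, 3), filters_per_width=4, k=4,
                        dropout_rate=0.5, learning_rate=1e-3, epochs=5,
                        batch_size=4, seed=11, patience=10)
        r1 = train(notes, y, notes, y, cfg, emb.copy())
        r2 = train(notes, y, notes, y, cfg, emb.copy())
        for h in r1.model.widths:
            assert np.array_equal(r1.model.filters[h], r2.model.filters[h])
        assert np.array_equal(r1.model.w_out, r2.model.w_out)
        assert np.array_equal(r1.model.embeddings, r2.model.embeddings)

    def test_planted_phrase_integration(self, planted_setup, trained_cnn):
        """On the planted-signal corpus the model separates held-out classes
        well — the deterministic-signal integration check."""
        s = planted_setup
        labels, probs = predict(trained_cnn.model, s.split_notes("test"),
                                trained_cnn.threshold)
        _, _, f1 = metrics(confusion(labels, s.split_y("test")))
        assert f1 >= 0.9


class TestPredict:
    def test_threshold_extremes(self):
        rng = np.random.default_rng(9)
        model = random_small_model(rng)
        notes = [rng.integers(1, 20, size=8) for _ in range(5)]
        lab0, _ = predict(model, notes, threshold=0.0)
        assert np.all(lab0 == 1)
        lab1, _ = predict(model, notes, threshold=1.0)
        assert np.all(lab1 == 0)

    def test_validation_threshold_self_consistency(self, planted_setup,
                                                   trained_cnn):
        """Re-applying the stored threshold to the validation split
        reproduces the stored validation F1."""
        s = planted_setup
        labels, _ = predict(trained_cnn.model, s.split_notes("val"),
                            trained_cnn.threshold)
        _, _, f1 = metrics(confusion(labels, s.split_y("val")))
        assert f1 == pytest.approx(trained_cnn.best_val_f1)


class TestPersistence:
    def test_save_load_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(10)
        model = random_small_model(rng)
        model.save(tmp_path / "ckpt")
        back = ConvModel.load(tmp_path / "ckpt")
        assert back.widths == model.widths
        for h in model.widths:
            assert np.array_equal(back.filters[h], model.filters[h])
            assert np.array_equal(back.biases[h], model.biases[h])
        assert np.array_equal(back.w_out, model.w_out)
        assert back.b_out == model.b_out
        assert np.array_equal(back.embeddings, model.embeddings)
        ids = rng.integers(1, 20, size=9)
        assert back.forward_note(ids).y == model.forward_note(ids).y
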