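"""Saliency: closed-form and finite-difference oracles, ranking rules,
highlight rendering."""

from __future__ import annotations

import numpy as np
import pytest

from phenotext.saliency import (GlobalPhraseRanking, SaliencyRecord,
                                global_top_phrases, highlight_note,
                                highlight_note_html, note_top_phrases,
                                phrase_saliency, word_saliency)

from conftest import random_small_model


def note_loss(model, ids, target=1) -> float:
    fwd = model.forward_note(ids)
    y = fwd.y
    return -np.log(y) if target == 1 else -np.log(1 - y)


class TestPhraseSaliency:
    def test_matches_closed_form_and_finite_differences(self):
        """|dL(1,y)/dc_hat_j| equals (1-y)|w_out_j| (rel 1e-6) and central
        finite differences on the pooled value (rel 1e-4)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            model = random_small_model(rng)
            ids = rng.integers(1, 20, size=int(rng.integers(5, 12)))
            tokens = [f"t{i}" for i in ids]
            fwd = model.forward_note(ids)
            records = phrase_saliency(model, tokens, ids, fwd=fwd)
            eps = 1e-4
            for rec, w_j in zip(records, model.w_out):
                closed = (1.0 - fwd.y) * abs(w_j)
                assert rec.score == pytest.approx(closed, rel=1e-6)
                # FD on the pooled value: perturb c_hat_j directly through
                # the output layer
                logit = fwd.logit
                lp = -np.log(1 / (1 + np.exp(-(logit + eps * w_j))))
                lm = -np.log(1 / (1 + np.exp(-(logit - eps * w_j))))
                fd = abs((lp - lm) / (2 * eps))
                if fd > 1e-8:
                    assert rec.score == pytest.approx(fd, rel=1e-4)

    def test_dead_output_weight_scores_zero(self):
        rng = np.random.default_rng(1)
        model = random_small_model(rng)
        model.w_out[:] = 0.0
        ids = rng.integers(1, 20, size=8)
        records = phrase_saliency(model, [f"t{i}" for i in ids], ids)
        assert all(r.score == 0.0 for r in records)

    def test_saturated_positive_has_vanishing_saliency(self):
        rng = np.random.default_rng(2)
        model = random_small_model(rng)
        model.b_out = 60.0  # logit >> 0 regardless of input
        ids = rng.integers(1, 20, size=8)
        records = phrase_saliency(model, [f"t{i}" for i in ids], ids)
        assert max(r.score for r in records) < 1e-10

    def test_record_window_matches_argmax_phrase(self):
        rng = np.random.default_rng(3)
        model = random_small_model(rng)
        ids = rng.integers(1, 20, size=10)
        tokens = [f"t{i}" for i in ids]
        fwd = model.forward_note(ids)
        slices = model.filter_slices()
        for rec in phrase_saliency(model, tokens, ids, fwd=fwd):
            h = rec.width
            j = rec.filter_index - slices[h].start
            assert rec.start == int(fwd.argmax[h][j])
            assert rec.phrase == " ".join(tokens[rec.start:rec.end])


class TestWordSaliency:
    def test_matches_finite_differences(self):
        """Per-token scores equal the L2 norm of dL(1,y)/dx_i, checked by
        perturbing individual embedding entries (distinct tokens so each
        position owns its row)."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            model = random_small_model(rng, vocab_size=16)
            n = 8
            ids = rng.permutation(np.arange(2, 2 + n))  # all distinct
            scores = word_saliency(model, ids)
            eps = 1e-5
            k = model.embeddings.shape[1]
            for pos in range(n):
                grad = np.zeros(k)
                row = ids[pos]
                for d in range(k):
                    orig = model.embeddings[row, d]
                    model.embeddings[row, d] = orig + eps
                    lp = note_loss(model, ids)
                    model.embeddings[row, d] = orig - eps
                    lm = note_loss(model, ids)
                    model.embeddings[row, d] = orig
                    grad[d] = (lp - lm) / (2 * eps)
                assert scores[pos] == pytest.approx(np.linalg.norm(grad),
                                                    rel=1e-3, abs=1e-8)

    def test_token_outside_active_windows_scores_zero(self):
        """With all feature maps inactive (large negative biases), every
        token's gradient is exactly zero."""
        rng = np.random.default_rng(5)
        model = random_small_model(rng)
        for h in model.widths:
            model.biases[h][:] = -100.0
        ids = rng.integers(1, 20, size=9)
        assert np.all(word_saliency(model, ids) == 0.0)

    def test_scores_are_nonnegative_and_per_position(self):
        rng = np.random.default_rng(6)
        model = random_small_model(rng)
        ids = np.array([3, 4, 3, 4, 3])  # duplicates at different positions
        scores = word_saliency(model, ids)
        assert len(scores) == 5
        assert np.all(scores >= 0)


class TestNoteTopPhrases:
    def test_single_filter_returns_its_argmax_window(self):
        rng = np.random.default_rng(7)
        model = random_small_model(rng, widths=(2,), m=1)
        ids = rng.integers(1, 20, size=9)
        tokens = [f"t{i}" for i in ids]
        [rec] = note_top_phrases(model, tokens, ids, top_k=1)
        fwd = model.forward_note(ids)
        assert rec.start == int(fwd.argmax[2][0])

    def test_same_window_deduplicated_to_max_score(self):
        rng = np.random.default_rng(8)
        model = random_small_model(rng, widths=(2,), m=4)
        ids = rng.integers(1, 20, size=9)
        tokens = [f"t{i}" for i in ids]
        records = phrase_saliency(model, tokens, ids)
        top = note_top_phrases(model, tokens, ids, top_k=50)
        windows = [(r.start, r.end) for r in top]
        assert len(windows) == len(set(windows))
        for rec in top:
            same = [r.score for r in records
                    if (r.start, r.end) == (rec.start, rec.end)]
            assert rec.score == max(same)

    def test_topk_beyond_windows_returns_all(self):
        rng = np.random.default_rng(9)
        model = random_small_model(rng, widths=(1, 2), m=2)
        ids = rng.integers(1, 20, size=6)
        tokens = [f"t{i}" for i in ids]
        top = note_top_phrases(model, tokens, ids, top_k=1000)
        assert len(top) <= 4  # at most one window per filter

    def test_invalid_topk(self):
        rng = np.random.default_rng(10)
        model = random_small_model(rng)
        with pytest.raises(ValueError):
            note_top_phrases(model, ["a"], np.array([2]), top_k=0)


class TestGlobalRanking:
    def _triple(self, rng, model, nid):
        ids = rng.integers(1, 20, size=10)
        return (nid, [f"t{i}" for i in ids], ids)

    def test_single_note_reduces_to_note_ranking(self):
        rng = np.random.default_rng(11)
        model = random_small_model(rng)
        nid, tokens, ids = self._triple(rng, model, "n1")
        ranking = global_top_phrases(model, [(nid, tokens, ids)], top_k=5)
        note_level = note_top_phrases(model, tokens, ids, top_k=5)
        # after phrase dedup the scores must coincide on the common prefix
        assert [r.score for r in ranking.entries] == pytest.approx(
            sorted({n.normalized_phrase(): n.score
                    for n in note_level}.values(), reverse=True)[:5])

    def test_duplicated_corpus_identical_ranking(self):
        rng = np.random.default_rng(12)
        model = random_small_model(rng)
        notes = [self._triple(rng, model, f"n{i}") for i in range(4)]
        r1 = global_top_phrases(model, notes, top_k=5)
        r2 = global_top_phrases(model, notes + notes, top_k=5)
        assert [(e.phrase, e.score) for e in r1.entries] == \
               [(e.phrase, e.score) for e in r2.entries]

    def test_corpus_order_invariance_of_topk_set(self):
        rng = np.random.default_rng(13)
        model = random_small_model(rng)
        notes = [self._triple(rng, model, f"n{i}") for i in range(5)]
        r1 = global_top_phrases(model, notes, top_k=5)
        r2 = global_top_phrases(model, notes[::-1], top_k=5)
        assert set(r1.phrases()) == set(r2.phrases())

    def test_scores_non_increasing_enforced(self):
        rec = lambda s: SaliencyRecord("n", 0, 1, 1, "x", s, 0)
        with pytest.raises(ValueError):
            GlobalPhraseRanking(entries=[rec(0.1), rec(0.5)])

    def test_empty_corpus_rejected(self):
        rng = np.random.default_rng(14)
        model = random_small_model(rng)
        with pytest.raises(ValueError):
            global_top_phrases(model, [], top_k=3)


class TestHighlighting:
    def test_no_records_text_unchanged(self):
        tokens = "a b c".split()
        assert highlight_note(tokens, []) == "a b c"

    def test_single_window_marked_once(self):
        tokens = "w1 alcohol abuse w2".split()
        rec = SaliencyRecord("n", 1, 3, 2, "alcohol abuse", 0.7, 0)
        out = highlight_note(tokens, [rec])
        assert out.count("[[") == 1
        assert "[[alcohol abuse|0.7]]" in out

    def test_overlapping_windows_merged_with_max_score(self):
        tokens = "a b c d e".split()
        recs = [SaliencyRecord("n", 0, 2, 2, "a b", 0.3, 0),
                SaliencyRecord("n", 1, 4, 3, "b c d", 0.9, 1)]
        out = highlight_note(tokens, recs)
        assert out == "[[a b c d|0.9]] e"

    def test_html_escapes_and_marks(self):
        tokens = ["x<y", "alcohol"]
        rec = SaliencyRecord("n", 1, 2, 1, "alcohol", 0.5, 0)
        out = highlight_note_html(tokens, [rec])
        assert "x&lt;y" in out
        assert "<mark" in out and "alcohol</mark>" in out
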