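"""Anchored-concept classifier: input construction, training contracts,
determinism, and behaviour on small separable data."""

import dataclasses

import numpy as np
import pytest

from aecoder.anchoring import CandidateInstance
from aecoder.classifier import (
    AnchoredConceptClassifier,
    EncoderConfig,
    TrainingConfig,
    build_input,
    tiny_training_config,
)
from aecoder.tokenization import WordPieceTokenizer


def _cand(concept, context, label="unknown", doc_id="d1", cui="C0000001"):
    return CandidateInstance(doc_id, cui, concept, context, label)


@pytest.fixture(scope="module")
def separable():
    """40 candidates whose label is fully determined by the cue adjacent
    to the anchor."""
    pos = ["patient developed [A] {} [/A] overnight",
           "admitted with [A] {} [/A] today"]
    neg = ["history of [A] {} [/A] noted",
           "no [A] {} [/A] seen"]
    concepts = ["tremor", "vomiting", "nausea", "rash",
                "dyspnea", "headache", "sepsis", "fatigue"]
    out = []
    for i in range(40):
        c = concepts[i % len(concepts)]
        frames, label = (pos, "positive") if i % 2 == 0 else (neg, "negative")
        out.append(_cand(c, frames[(i // 2) % 2].format(c),
                         label, doc_id=f"d{i}"))
    return out


@pytest.fixture(scope="module")
def tok(separable):
    texts = [c.concept_text for c in separable] + [c.anchored_text for c in separable]
    return WordPieceTokenizer.train(texts, vocab_size=500)


class TestBuildInput:
    def test_sequence_pair_layout(self, tok):
        cand = _cand("tremor", "patient developed [A] tremor [/A]")
        enc = build_input(cand, EncoderConfig.tiny(), tok)
        toks = list(enc.tokens)
        assert toks[0] == "[CLS]"
        first_sep = toks.index("[SEP]")
        assert toks[1:first_sep] == ["tremor"]
        assert toks[-1] == "[SEP]"
        assert "[A]" in toks[first_sep:] and "[/A]" in toks[first_sep:]
        # segment ids: 0 through the first [SEP], 1 afterwards
        np.testing.assert_array_equal(
            enc.segment_ids[: first_sep + 1], 0
        )
        np.testing.assert_array_equal(enc.segment_ids[first_sep + 1 :], 1)

    def test_token_count_recount(self, tok):
        cand = _cand("chest pain", "no [A] chest pain [/A] or dyspnea seen")
        enc = build_input(cand, EncoderConfig.tiny(), tok)
        seg_a = tok.tokenize_text(cand.concept_text)
        seg_b = tok.tokenize_text(cand.anchored_text)
        assert len(enc.tokens) == 3 + len(seg_a) + len(seg_b)

    def test_truncation_only_from_segment_b_right(self, tok):
        context = "admitted with [A] tremor [/A] " + "stable " * 100
        cand = _cand("tremor", context)
        cfg = dataclasses.replace(EncoderConfig.tiny(), max_sequence_length=32)
        enc = build_input(cand, cfg, tok)
        assert len(enc.tokens) == 32
        toks = list(enc.tokens)
        assert "[/A]" in toks  # anchor region survives truncation

    def test_truncation_cannot_drop_first_anchor(self, tok):
        context = "stable " * 100 + "admitted with [A] tremor [/A]"
        cand = _cand("tremor", context)
        cfg = dataclasses.replace(EncoderConfig.tiny(), max_sequence_length=16)
        with pytest.raises(ValueError, match="anchor"):
            build_input(cand, cfg, tok)

    def test_empty_context_rejected(self, tok):
        with pytest.raises(ValueError, match="empty context"):
            build_input(_cand("tremor", "   "), EncoderConfig.tiny(), tok)

    def test_oversized_concept_rejected(self, tok):
        cand = _cand("tremor " * 40, "patient developed [A] tremor [/A]")
        cfg = dataclasses.replace(EncoderConfig.tiny(), max_sequence_length=16)
        with pytest.raises(ValueError, match="concept_text"):
            build_input(cand, cfg, tok)


class TestConfigs:
    def test_published_training_defaults(self):
        tc = TrainingConfig()
        assert tc.epochs == 8
        assert tc.batch_size == 8
        assert tc.learning_rate == 2e-5
        assert tc.clip_norm == 1.0
        assert tc.warmup_steps == 100
        assert tc.dropout == 0.1
        assert tc.head_init_sd == 0.02
        assert tc.word_dropout == 0.0

    def test_encoder_presets(self):
        base = EncoderConfig.paper_base()
        assert (base.layers, base.hidden_size, base.attention_heads) == (12, 768, 12)
        tiny = EncoderConfig.tiny()
        assert (tiny.layers, tiny.hidden_size, tiny.attention_heads) == (2, 64, 4)

    def test_heads_must_divide_hidden(self):
        with pytest.raises(ValueError):
            EncoderConfig(hidden_size=10, attention_heads=3)


@pytest.fixture(scope="module")
def fitted(separable):
    return AnchoredConceptClassifier(training=tiny_training_config(seed=7)).fit(separable)


class TestTraining:
    def test_separable_corpus_training_accuracy(self, fitted, separable):
        pred = fitted.predict(separable)
        gold = np.array([c.label == "positive" for c in separable])
        assert (pred == gold).mean() == 1.0

    def test_seeded_rerun_identical_labels(self, separable, fitted):
        again = AnchoredConceptClassifier(
            training=tiny_training_config(seed=7)
        ).fit(separable)
        np.testing.assert_array_equal(
            again.predict(separable), fitted.predict(separable)
        )

    def test_single_class_rejected(self, separable):
        pos_only = [c for c in separable if c.label == "positive"]
        with pytest.raises(ValueError, match="negative"):
            AnchoredConceptClassifier(training=tiny_training_config()).fit(pos_only)

    def test_too_few_candidates_rejected(self, separable):
        with pytest.raises(ValueError):
            AnchoredConceptClassifier().fit(separable[:1])

    def test_shuffled_labels_near_chance(self, separable):
        rng = np.random.default_rng(3)
        labels = [c.label for c in separable]
        shuffled = list(rng.permutation(labels))
        noisy = [dataclasses.replace(c, label=l)
                 for c, l in zip(separable[:32], shuffled[:32])]
        held = [dataclasses.replace(c, label=l)
                for c, l in zip(separable[32:], shuffled[32:])]
        tc = dataclasses.replace(tiny_training_config(seed=5), epochs=8)
        clf = AnchoredConceptClassifier(training=tc).fit(noisy)
        gold = np.array([c.label == "positive" for c in held])
        acc = (clf.predict(held) == gold).mean()
        assert abs(acc - 0.5) <= 0.35


class TestPrediction:
    def test_probability_pairs_sum_to_one(self, fitted, separable):
        probs = fitted.predict_proba(separable)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_candidate_identical_probability(self, fitted, separable):
        c = separable[0]
        p = fitted.predict_proba([c, c])[:, 1]
        assert p[0] == p[1]

    def test_batch_composition_invariance(self, fitted, separable):
        probs_all = fitted.predict_proba(separable)[:, 1]
        probs_small = np.concatenate(
            [fitted.predict_proba(separable[i : i + 3])[:, 1]
             for i in range(0, len(separable), 3)]
        )
        np.testing.assert_allclose(probs_all, probs_small, atol=1e-5)

    def test_probabilities_concentrated_at_extremes(self, fitted, separable):
        probs = fitted.predict_proba(separable)[:, 1]
        assert np.mean((probs < 0.2) | (probs > 0.8)) >= 0.8

    def test_prediction_records_provenance(self, fitted, separable):
        preds = fitted.predict_candidates(separable[:5])
        assert [p.doc_id for p in preds] == [c.doc_id for c in separable[:5]]
        for p in preds:
            z = np.array(p.logits)
            soft = np.exp(z - z.max())
            soft = soft / soft.sum()
            assert p.prob_positive == pytest.approx(float(soft[1]), abs=1e-6)

    def test_softmax_consistency_with_threshold(self, fitted, separable):
        preds = fitted.predict_candidates(separable)
        for p in preds:
            expected = "positive" if p.prob_positive >= 0.5 else "negative"
            assert p.predicted_label == expected


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, fitted, separable):
        d = tmp_path / "model"
        fitted.save(d)
        loaded = AnchoredConceptClassifier.load(d)
        np.testing.assert_allclose(
            loaded.predict_proba(separable), fitted.predict_proba(separable),
            atol=1e-6,
        )

    def test_pretrained_mode_reuses_checkpoint(self, tmp_path, fitted, separable):
        d = tmp_path / "ckpt"
        fitted.save(d)
        enc = dataclasses.replace(fitted.encoder_, pretrained=str(d))
        tc = dataclasses.replace(tiny_training_config(seed=1), epochs=1)
        warm = AnchoredConceptClassifier(encoder=enc, training=tc).fit(separable)
        gold = np.array([c.label == "positive" for c in separable])
        assert (warm.predict(separable) == gold).mean() == 1.0


def test_sklearn_clone_compatible():
    from sklearn.base import clone

    est = AnchoredConceptClassifier(training=tiny_training_config(seed=3))
    cloned = clone(est)
    assert cloned.get_params()["training"] == est.get_params()["training"]
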