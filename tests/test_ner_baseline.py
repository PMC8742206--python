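"""BIO encoding/decoding, exact-span scoring, CUI-level coding of
extracted phrases, and the tagger training contract."""

import dataclasses

import numpy as np
import pytest

from aecoder.anchoring import GoldLabeling
from aecoder.classifier import tiny_training_config
from aecoder.evaluation import prf
from aecoder.ner_baseline import (
    BioSpanTagger,
    bio_encode,
    code_and_evaluate,
    decode_bio,
    evaluate_ner,
)
from aecoder._tokens import tokenize_with_offsets


class TestBioEncode:
    def test_single_token_span(self):
        tagged = bio_encode("patient developed tremor", [(18, 24)])
        assert [t.bio_label for t in tagged] == ["O", "O", "B"]

    def test_multi_token_span(self):
        text = "no respiratory tract infection seen"
        tagged = bio_encode(text, [(3, 30)])
        assert [t.bio_label for t in tagged] == ["O", "B", "I", "I", "O"]

    def test_no_spans_all_outside(self):
        tagged = bio_encode("entirely unremarkable", [])
        assert all(t.bio_label == "O" for t in tagged)

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            bio_encode("a b c d", [(0, 3), (2, 5)])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            bio_encode("a b", [(0, 99)])

    def test_encode_decode_round_trip_random(self, rng):
        words = ["alpha", "beta", "gamma", "delta", "eps", "zeta", "eta"]
        for _ in range(50):
            n = int(rng.integers(3, 12))
            text = " ".join(words[int(rng.integers(len(words)))] for _ in range(n))
            toks = tokenize_with_offsets(text)
            spans = []
            i = 0
            while i < len(toks):
                if rng.random() < 0.3:
                    j = min(len(toks), i + int(rng.integers(1, 3)))
                    spans.append((toks[i][1], toks[j - 1][2]))
                    i = j + 1
                else:
                    i += 1
            tagged = bio_encode(text, spans)
            decoded = decode_bio(
                [t.bio_label for t in tagged], [(s, e) for _, s, e in toks]
            )
            assert decoded == sorted(spans)


class TestDecodeRepair:
    def test_illegal_initial_i_promoted_to_b(self):
        offsets = [(0, 1), (2, 3), (4, 5)]
        assert decode_bio(["I", "O", "O"], offsets) == [(0, 1)]

    def test_i_after_o_promoted(self):
        offsets = [(0, 1), (2, 3), (4, 5)]
        assert decode_bio(["O", "I", "I"], offsets) == [(2, 5)]

    def test_adjacent_b_b_two_spans(self):
        offsets = [(0, 1), (2, 3)]
        assert decode_bio(["B", "B"], offsets) == [(0, 1), (2, 3)]


class TestEvaluateNer:
    def test_identical_sets_perfect(self):
        spans = [(0, 5), (8, 12)]
        m = prf(evaluate_ner(spans, spans))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_partial_overlap_is_a_miss(self):
        counts = evaluate_ner([(0, 4)], [(0, 5)])
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_random_sets_match_hand_enumeration(self, rng):
        for _ in range(40):
            pred = {(int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 20, 4), rng.integers(1, 4, 4))}
            gold = {(int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 20, 4), rng.integers(1, 4, 4))}
            counts = evaluate_ner(sorted(pred), sorted(gold))
            tp = len(pred & gold)
            assert (counts.tp, counts.fp, counts.fn) == (
                tp, len(pred) - tp, len(gold) - tp,
            )


class TestCodeAndEvaluate:
    def test_truncated_phrase_codes_to_broader_concept(self, lexicon):
        # the classic boundary error: "tract infection" instead of the full
        # phrase codes to the broader infection concept -> 1 FP and 1 FN
        text = "admitted with respiratory tract infection today"
        gold = {"d1": GoldLabeling("d1", {"C0035243"})}
        start = text.index("tract")
        end = start + len("tract infection")
        counts = code_and_evaluate(
            {"d1": [(start, end)]}, {"d1": text}, lexicon, gold
        )
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_correct_phrase_codes_exactly(self, lexicon):
        text = "admitted with respiratory tract infection today"
        gold = {"d1": GoldLabeling("d1", {"C0035243"})}
        s = text.index("respiratory")
        counts = code_and_evaluate(
            {"d1": [(s, s + len("respiratory tract infection"))]},
            {"d1": text}, lexicon, gold,
        )
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    def test_uncodable_phrases_dropped(self, lexicon):
        gold = {"d1": GoldLabeling("d1", set())}
        counts = code_and_evaluate(
            {"d1": [(0, 9)]}, {"d1": "zzz qq ww"}, lexicon, gold
        )
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 0)

    def test_coded_cuis_never_outside_lexicon(self, lexicon, rng):
        words = ["tremor", "vomiting", "zzz", "infection", "tract"]
        for _ in range(20):
            text = " ".join(words[int(rng.integers(len(words)))] for _ in range(6))
            spans = [(0, len(text))]
            counts = code_and_evaluate(
                {"d": spans}, {"d": text}, lexicon,
                {"d": GoldLabeling("d", set())},
            )
            # any predicted CUI shows up as FP against empty gold; all of
            # them must resolve in the lexicon by construction
            assert counts.fp <= 1


class TestTaggerContract:
    @pytest.fixture(scope="class")
    def tiny_docs(self):
        texts = [
            "patient developed tremor today",
            "history of vomiting noted",
            "admitted with rash overnight",
            "no headache reported",
            "patient developed nausea today",
            "history of dizziness noted",
        ]
        spans = [
            [(18, 24)], [], [(14, 18)], [], [(18, 24)], [],
        ]
        return texts, spans

    def test_training_requires_spans(self, tiny_docs):
        texts, _ = tiny_docs
        with pytest.raises(ValueError, match="positive"):
            BioSpanTagger(training=tiny_training_config()).fit(
                texts, [[] for _ in texts]
            )

    def test_seeded_rerun_identical_spans(self, tiny_docs):
        texts, spans = tiny_docs
        tc = dataclasses.replace(tiny_training_config(seed=3), epochs=4)
        a = BioSpanTagger(training=tc).fit(texts, spans).predict(texts)
        b = BioSpanTagger(training=tc).fit(texts, spans).predict(texts)
        assert a == b

    def test_empty_document_no_spans(self, tiny_docs):
        texts, spans = tiny_docs
        tc = dataclasses.replace(tiny_training_config(seed=3), epochs=2)
        tagger = BioSpanTagger(training=tc).fit(texts, spans)
        assert tagger.predict([""]) == [[]]
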