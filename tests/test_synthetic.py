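"""Synthetic corpus generator: statistical shape, determinism, bookkeeping
reconciliation, the simulated second annotator, and the hard cases."""

import numpy as np
import pytest

from aecoder._tokens import tokenize
from aecoder.agreement import compare
from aecoder.anchoring import LABEL_POSITIVE
from aecoder.evaluation import prf
from aecoder.lexicon import find_concept_mentions
from aecoder.pipeline import prepare_documents
from aecoder.synthetic import (
    PARAPHRASES,
    GeneratorConfig,
    generate_corpus,
    hard_case_fixtures,
    simulate_second_annotator,
    write_hard_cases,
)


@pytest.fixture(scope="module")
def corpus(lexicon):
    return generate_corpus(GeneratorConfig(n_documents=200, seed=1), lexicon)


class TestCorpusShape:
    def test_document_length_target(self, corpus):
        mean_tokens = np.mean([len(tokenize(t)) for t in corpus.texts.values()])
        assert abs(mean_tokens - 37.0) <= 5.0

    def test_positive_candidate_fraction_target(self, corpus):
        labels = [
            lab
            for d in corpus.true_candidate_labels.values()
            for lab in d.values()
        ]
        frac = sum(1 for lab in labels if lab == LABEL_POSITIVE) / len(labels)
        assert abs(frac - 0.662) <= 0.05

    def test_statistics_converge_at_large_n(self, lexicon):
        big = generate_corpus(GeneratorConfig(n_documents=1000, seed=3), lexicon)
        mean_tokens = np.mean([len(tokenize(t)) for t in big.texts.values()])
        mean_labels = np.mean(
            [len(g.gold_cuis) for g in big.gold_labels.values()]
        )
        labels = [
            lab for d in big.true_candidate_labels.values() for lab in d.values()
        ]
        frac = sum(1 for lab in labels if lab == LABEL_POSITIVE) / len(labels)
        assert abs(mean_tokens - 37.0) <= 3.0
        assert abs(mean_labels - 3.5) <= 0.3
        assert abs(frac - 0.662) <= 0.03

    def test_deterministic_under_seed(self, lexicon):
        a = generate_corpus(GeneratorConfig(n_documents=20, seed=5), lexicon)
        b = generate_corpus(GeneratorConfig(n_documents=20, seed=5), lexicon)
        assert a.texts == b.texts
        assert a.gold_annotations == b.gold_annotations
        assert a.planted_misses == b.planted_misses

    def test_gold_spans_match_text_slices(self, corpus):
        for doc_id, anns in corpus.gold_annotations.items():
            text = corpus.texts[doc_id]
            for a in anns:
                assert text[a.start : a.end] == a.text

    def test_infeasible_config_rejected(self, lexicon):
        cfg = GeneratorConfig(n_documents=5, seed=0, mean_labels_per_doc=60.0)
        with pytest.raises(ValueError):
            generate_corpus(cfg, lexicon)


class TestBookkeeping:
    def test_no_misses_when_rate_zero(self, lexicon):
        c = generate_corpus(
            GeneratorConfig(n_documents=40, seed=2, lookup_miss_rate=0.0), lexicon
        )
        _, missed = prepare_documents(c.texts, c.gold_labels, lexicon)
        assert all(not m for m in missed.values())

    def test_pipeline_recovers_generator_labels_exactly(self, lexicon):
        c = generate_corpus(
            GeneratorConfig(n_documents=40, seed=2, lookup_miss_rate=0.0), lexicon
        )
        cands, _ = prepare_documents(c.texts, c.gold_labels, lexicon)
        for doc_id in c.texts:
            recovered = {x.cui: x.label for x in cands[doc_id]}
            assert recovered == c.true_candidate_labels[doc_id]

    def test_conservation_positives_plus_misses(self, corpus, lexicon):
        # across the corpus: positive candidates + lookup misses = gold labels
        cands, missed = prepare_documents(corpus.texts, corpus.gold_labels, lexicon)
        for doc_id in corpus.texts:
            n_pos = sum(1 for x in cands[doc_id] if x.label == LABEL_POSITIVE)
            assert n_pos + len(missed[doc_id]) == len(
                corpus.gold_labels[doc_id].gold_cuis
            )

    def test_paraphrases_invisible_to_lookup(self, lexicon):
        for phrase in PARAPHRASES.values():
            assert find_concept_mentions(phrase, lexicon) == []


class TestSecondAnnotator:
    def test_zero_rates_identical(self, corpus):
        anns = simulate_second_annotator(corpus, miss_rate=0.0, spurious_rate=0.0)
        gold = [a for d in corpus.doc_ids for a in corpus.gold_annotations[d]]
        counts, _ = compare(gold, anns)
        assert counts.fp == 0 and counts.fn == 0
        assert prf(counts).f1 == 1.0

    def test_total_miss_drops_everything(self, corpus):
        anns = simulate_second_annotator(corpus, miss_rate=1.0, spurious_rate=0.0)
        gold = [a for d in corpus.doc_ids for a in corpus.gold_annotations[d]]
        counts, _ = compare(gold, anns)
        assert counts.tp == 0

    def test_default_rates_give_published_scale_agreement(self, lexicon):
        # binomial expectation: miss 98/842, spurious 50/842 => F1 near 0.91
        big = generate_corpus(GeneratorConfig(n_documents=250, seed=11), lexicon)
        f1s = []
        for seed in (1, 2, 3):
            anns = simulate_second_annotator(big, seed=seed)
            gold = [a for d in big.doc_ids for a in big.gold_annotations[d]]
            counts, _ = compare(gold, anns)
            f1s.append(prf(counts).f1)
        assert abs(np.mean(f1s) - 0.91) <= 0.02


class TestHardCases:
    def test_every_cui_resolves_in_toy_lexicon(self, lexicon):
        for c in hard_case_fixtures(lexicon):
            assert c.cui in lexicon

    def test_polarity_pair_present(self, lexicon):
        cands = hard_case_fixtures(lexicon)
        mobility = [c for c in cands if c.cui == "C0587597"]
        pain = [c for c in cands if c.doc_id == "hc-polarity-neg"]
        assert mobility and mobility[0].label == "positive"
        assert pain and all(c.label == "negative" for c in pain)

    def test_negation_cases_labeled_negative(self, lexicon):
        cands = hard_case_fixtures(lexicon)
        neg1 = [c for c in cands if c.doc_id == "hc-negation-1"]
        assert len(neg1) >= 2
        assert all(c.label == "negative" for c in neg1)

    def test_serialization_byte_stable(self, tmp_path, lexicon):
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_hard_cases(p1, lexicon)
        write_hard_cases(p2, lexicon)
        assert p1.read_bytes() == p2.read_bytes()
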