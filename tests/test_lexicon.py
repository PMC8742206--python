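"""Dictionary lookup: leftmost-longest matching, semantic-type filtering,
phrase coding, and equivalence with a brute-force oracle."""

import numpy as np
import pytest

from aecoder._tokens import tokenize_with_offsets
from aecoder.lexicon import (
    Lexicon,
    LexiconEntry,
    LexiconError,
    LexiconParseError,
    SemanticTypeFilter,
    code_phrase,
    find_concept_mentions,
    load_lexicon,
)


def _entry(cui, term, st="sign or symptom", preferred=True):
    return LexiconEntry(cui, term, st, preferred)


class TestLoading:
    def test_load_toy_lexicon(self, lexicon):
        assert len(lexicon) > 50
        assert lexicon.preferred_name("C0035243") == "respiratory tract infection"

    def test_two_known_concepts(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text(
            "cui\tsemantic_type\tterm\tpreferred\n"
            "C0035243\tdisease or syndrome\trespiratory tract infection\t1\n"
            "C3714514\tdisease or syndrome\tinfection\t1\n"
        )
        lex = load_lexicon(p)
        assert lex.cuis == {"C0035243", "C3714514"}

    def test_empty_lexicon_finds_nothing(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("cui\tsemantic_type\tterm\tpreferred\n")
        lex = load_lexicon(p)
        assert find_concept_mentions("patient developed tremor", lex) == []

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text(
            "cui\tsemantic_type\tterm\tpreferred\n"
            "C0000001\tfinding\tfoo\t1\n"
            "garbage-no-tabs\n"
        )
        with pytest.raises(LexiconParseError, match="line 3"):
            load_lexicon(p)

    @pytest.mark.parametrize("n_preferred", [0, 2])
    def test_preferred_uniqueness_enforced(self, n_preferred):
        flags = [i < n_preferred for i in range(2)]
        entries = [
            _entry("C0000001", f"term {i}", preferred=f) for i, f in enumerate(flags)
        ]
        with pytest.raises(LexiconError, match="preferred"):
            Lexicon(entries)

    def test_duplicate_rows_deduplicated(self):
        lex = Lexicon(
            [_entry("C0000001", "tremor"), _entry("C0000001", "tremor")]
        )
        assert len(lex.entries) == 1

    def test_invalid_cui_rejected(self):
        with pytest.raises(LexiconError, match="CUI"):
            Lexicon([_entry("X123", "tremor")])

    def test_shared_synonym_tie_breaks_to_lower_cui(self):
        lex = Lexicon(
            [
                _entry("C0000002", "growth", "neoplastic process"),
                _entry("C0000002", "tumour", "neoplastic process", preferred=False),
                _entry("C0000001", "mass", "neoplastic process"),
                _entry("C0000001", "tumour", "neoplastic process", preferred=False),
            ]
        )
        ms = find_concept_mentions("large tumour seen", lex)
        assert [m.cui for m in ms] == ["C0000001"]


class TestMatching:
    def test_longest_phrase_wins(self, lexicon):
        ms = find_concept_mentions(
            "admitted with lower respiratory tract infection", lexicon
        )
        assert len(ms) == 1
        assert ms[0].cui == "C0035243"
        assert ms[0].matched_text == "respiratory tract infection"

    def test_no_match_inside_words(self):
        # token boundaries: "art" must not match inside "heart"
        lex = Lexicon([_entry("C0000001", "art")])
        assert find_concept_mentions("heart rate normal", lex) == []

    def test_semantic_type_filter_monotone(self, lexicon):
        text = "patient developed tremor and respiratory tract infection"
        full = find_concept_mentions(text, lexicon)
        flt = SemanticTypeFilter().without("sign or symptom")
        restricted = find_concept_mentions(text, lexicon, flt)
        assert len(restricted) <= len(full)
        assert all(m.semantic_type != "sign or symptom" for m in restricted)

    def test_offsets_reproduce_slices(self, lexicon):
        text = "no pleural effusion or pneumothorax today"
        for m in find_concept_mentions(text, lexicon):
            assert text[m.start : m.end] == m.matched_text

    def test_mentions_never_overlap_and_sorted(self, lexicon):
        text = "chest pain and back pain with pain elsewhere and chest pain"
        ms = find_concept_mentions(text, lexicon)
        assert ms == sorted(ms, key=lambda m: m.start)
        for a, b in zip(ms, ms[1:]):
            assert a.end <= b.start


def _brute_force(text, lexicon, flt):
    """Enumerate every token-boundary substring; resolve leftmost-longest."""
    toks = tokenize_with_offsets(text.lower())
    words = [t[0] for t in toks]
    found = []
    i = 0
    while i < len(words):
        best = None
        for j in range(len(words), i, -1):
            cands = [
                e
                for e in lexicon.entries
                if tuple(e.term.split()) == tuple(words[i:j])
                and e.semantic_type in flt
            ]
            if cands:
                best = (min(c.cui for c in cands), j)
                break
        if best is None:
            i += 1
        else:
            cui, j = best
            found.append((cui, toks[i][1], toks[j - 1][2]))
            i = j
    return found


class TestOracle:
    def test_matches_brute_force_on_random_texts(self, lexicon, rng):
        vocab = [e.term for e in lexicon.entries] + [
            "the", "patient", "was", "noted", "stable", "review", "on", "ward",
        ]
        flt = SemanticTypeFilter()
        for _ in range(120):
            words = []
            for _ in range(rng.integers(5, 40)):
                words.append(vocab[int(rng.integers(len(vocab)))])
            text = " ".join(words)
            fast = [
                (m.cui, m.start, m.end) for m in find_concept_mentions(text, lexicon)
            ]
            assert fast == _brute_force(text, lexicon, flt)


class TestCodePhrase:
    @pytest.mark.parametrize(
        "phrase,expected",
        [
            ("urinary tract infection", "C0042029"),
            ("tract infection", "C3714514"),
            ("qqq zzz", None),
        ],
    )
    def test_paper_degradation_examples(self, lexicon, phrase, expected):
        assert code_phrase(phrase, lexicon) == expected

    def test_exact_match_beats_contained_term(self, lexicon):
        # full phrase in the lexicon wins over any longer contained term
        assert code_phrase("respiratory tract infection", lexicon) == "C0035243"

    def test_empty_phrase_rejected(self, lexicon):
        with pytest.raises(ValueError):
            code_phrase("  ", lexicon)
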