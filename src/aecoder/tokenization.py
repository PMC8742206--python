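"""WordPiece-style subword tokenization trained on the working corpus.

Subword units let the classifier exploit lexical morphology (prefixes such
as *hypo-*, suffixes such as *-emia*) instead of treating rare clinical
terms as opaque unknowns.  The vocabulary is learned with the usual
bottom-up pair-merging procedure (characters up to frequent subwords, with
``##`` marking word-internal continuation pieces) and applied with the
greedy longest-match-first segmentation.  Reserved marker tokens — the
anchor markers among them — are atomic and never fragmented.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from ._tokens import tokenize

__all__ = ["SPECIAL_TOKENS", "WordPieceTokenizer"]

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
ANCHOR_OPEN, ANCHOR_CLOSE = "[A]", "[/A]"
SPECIAL_TOKENS = [PAD, UNK, CLS, SEP, ANCHOR_OPEN, ANCHOR_CLOSE]


_MARKER_LOWER = {ANCHOR_OPEN.lower(): ANCHOR_OPEN, ANCHOR_CLOSE.lower(): ANCHOR_CLOSE}


def _word_to_units(word: str) -> tuple[str, ...]:
    return tuple([word[0]] + ["##" + c for c in word[1:]])


def _iter_words(text: str):
    """Yield lowercase surface words, keeping anchor markers atomic."""
    for chunk in text.lower().split():
        marker = _MARKER_LOWER.get(chunk)
        if marker is not None:
            yield marker
        else:
            yield from tokenize(chunk)


class WordPieceTokenizer:
    """Greedy longest-match subword tokenizer with a learned vocabulary."""

    def __init__(self, vocab: Sequence[str]):
        self.id_to_token = list(vocab)
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")
        for tok in SPECIAL_TOKENS:
            if tok not in self.token_to_id:
                raise ValueError(f"vocabulary missing special token {tok}")
        self._max_piece = max(
            (len(t) for t in self.id_to_token if not t.startswith("[")), default=1
        )

    # -- construction -----------------------------------------------------
    @classmethod
    def train(
        cls,
        texts: Iterable[str],
        vocab_size: int = 2000,
        min_pair_freq: int = 2,
    ) -> "WordPieceTokenizer":
        """Learn a subword vocabulary from raw texts.

        Starts from single characters (word-initial and ``##`` continuation
        forms) and repeatedly merges the most frequent adjacent pair until
        *vocab_size* is reached or no pair occurs *min_pair_freq* times.
        Ties break lexicographically for determinism.
        """
        word_freq: dict[str, int] = {}
        for text in texts:
            for w in _iter_words(text):
                if w in (ANCHOR_OPEN, ANCHOR_CLOSE):
                    continue
                word_freq[w] = word_freq.get(w, 0) + 1

        words: dict[tuple[str, ...], int] = {
            _word_to_units(w): f for w, f in word_freq.items()
        }
        vocab: dict[str, None] = {}
        for units in words:
            for u in units:
                vocab.setdefault(u, None)

        budget = vocab_size - len(SPECIAL_TOKENS)
        while len(vocab) < budget:
            pair_freq: dict[tuple[str, str], int] = {}
            for units, f in words.items():
                for a, b in zip(units, units[1:]):
                    pair_freq[(a, b)] = pair_freq.get((a, b), 0) + f
            if not pair_freq:
                break
            (a, b), best = max(
                pair_freq.items(), key=lambda kv: (kv[1], kv[0])
            )
            if best < min_pair_freq:
                break
            merged = a + b[2:] if b.startswith("##") else a + b
            vocab.setdefault(merged, None)
            new_words: dict[tuple[str, ...], int] = {}
            for units, f in words.items():
                out: list[str] = []
                i = 0
                while i < len(units):
                    if i + 1 < len(units) and units[i] == a and units[i + 1] == b:
                        out.append(merged)
                        i += 2
                    else:
                        out.append(units[i])
                        i += 1
                new_words[tuple(out)] = new_words.get(tuple(out), 0) + f
            words = new_words

        ordered = SPECIAL_TOKENS + sorted(vocab)
        return cls(ordered)

    # -- application ------------------------------------------------------
    def tokenize_word(self, word: str) -> list[str]:
        """Greedy longest-match-first segmentation of one word."""
        if word in self.token_to_id:
            return [word]
        pieces: list[str] = []
        i = 0
        while i < len(word):
            end = min(len(word), i + self._max_piece)
            piece = None
            while end > i:
                cand = word[i:end] if i == 0 else "##" + word[i:end]
                if cand in self.token_to_id:
                    piece = cand
                    break
                end -= 1
            if piece is None:
                return [UNK]
            pieces.append(piece)
            i = end
        return pieces

    def tokenize_text(self, text: str) -> list[str]:
        """Segment whole text; anchor markers stay atomic."""
        pieces: list[str] = []
        for w in _iter_words(text):
            if w in (ANCHOR_OPEN, ANCHOR_CLOSE):
                pieces.append(w)
            else:
                pieces.extend(self.tokenize_word(w))
        return pieces

    def convert_tokens_to_ids(self, tokens: Sequence[str]) -> list[int]:
        unk = self.token_to_id[UNK]
        return [self.token_to_id.get(t, unk) for t in tokens]

    @property
    def vocab_size(self) -> int:
        return len(self.id_to_token)

    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.id_to_token, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "WordPieceTokenizer":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))
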