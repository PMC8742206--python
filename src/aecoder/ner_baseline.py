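"""The competing extract-then-code baseline.

Instead of looking concepts up first and classifying them in context, the
baseline fine-tunes the same transformer encoder for BIO span tagging of
adverse-event phrases and codes each extracted phrase against the lexicon
afterwards.  It is evaluated two ways: exact span match (the NER task
itself) and CUI-level end-to-end coding, where a truncated extraction such
as ``tract infection`` codes to the broader ``infection`` concept and is
scored as both a false positive and a false negative.

Subword pieces inherit their word's label; only the first piece of each
word is scored or decoded.  Decoding repairs illegal transitions by
promoting an ``I`` that follows ``O`` (or document start) to ``B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone

from ._tokens import tokenize_with_offsets
from .anchoring import GoldLabeling
from .classifier import EncoderConfig, TrainingConfig, tiny_training_config
from .evaluation import ConfusionCounts, Metrics, prf
from .lexicon import Lexicon, SemanticTypeFilter, code_phrase
from .nn import Adam, LinearWarmupSchedule, TokenTaggerNet, TransformerEncoder
from .nn import autograd as ag
from .tokenization import CLS, SEP, WordPieceTokenizer

__all__ = [
    "TaggedToken",
    "bio_encode",
    "decode_bio",
    "BioSpanTagger",
    "train_tagger",
    "predict_spans",
    "evaluate_ner",
    "code_and_evaluate",
    "BaselineReport",
    "cross_validate_tagger",
]

_O, _B, _I = 0, 1, 2
_LABEL_NAMES = {_O: "O", _B: "B", _I: "I"}


@dataclass(frozen=True)
class TaggedToken:
    token: str
    bio_label: str


def bio_encode(text: str, spans: Sequence[tuple[int, int]]) -> list[TaggedToken]:
    """Label the words of *text* with B/I/O according to gold *spans*."""
    spans = sorted(spans)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping gold spans ({s1},{e1}) and ({s2},{e2})")
    for s, e in spans:
        if not (0 <= s < e <= len(text)):
            raise ValueError(f"span ({s},{e}) out of document bounds")
    toks = tokenize_with_offsets(text)
    out: list[TaggedToken] = []
    for i, (tok, ts, te) in enumerate(toks):
        label = "O"
        for s, e in spans:
            if ts >= s and te <= e:
                prev_in = i > 0 and toks[i - 1][1] >= s and toks[i - 1][2] <= e
                label = "I" if prev_in else "B"
                break
        out.append(TaggedToken(tok, label))
    return out


def decode_bio(
    labels: Sequence[str],
    token_offsets: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Turn word-level B/I/O labels into character spans.

    An ``I`` after ``O`` or at document start is repaired to ``B``.
    """
    spans: list[tuple[int, int]] = []
    start: Optional[int] = None
    end = 0
    for label, (ts, te) in zip(labels, token_offsets, strict=True):
        if label == "I" and start is None:
            label = "B"  # repair illegal transition
        if label == "B":
            if start is not None:
                spans.append((start, end))
            start, end = ts, te
        elif label == "I":
            end = te
        else:
            if start is not None:
                spans.append((start, end))
                start = None
    if start is not None:
        spans.append((start, end))
    return spans


class BioSpanTagger(BaseEstimator):
    """Transformer BIO tagger over normalized documents (sklearn-style).

    ``fit(X, y)`` takes documents as plain texts and ``y`` as lists of
    gold (start, end) character spans per document; ``predict(X)`` returns
    predicted span lists.  The encoder and training regime mirror the
    anchored classifier's.
    """

    def __init__(self, encoder: Optional[EncoderConfig] = None,
                 training: Optional[TrainingConfig] = None):
        self.encoder = encoder
        self.training = training

    def fit(self, X: Sequence[str], y: Sequence[Sequence[tuple[int, int]]]):
        texts = list(X)
        all_spans = [list(s) for s in y]
        if len(texts) != len(all_spans):
            raise ValueError("X and y must have equal length")
        if len(texts) < 2:
            raise ValueError("need at least 2 training documents")
        if not any(all_spans):
            raise ValueError("training set lacks the positive class (no spans)")

        enc = self.encoder or EncoderConfig.tiny()
        tc = self.training or tiny_training_config()
        rng = np.random.default_rng(tc.seed)
        self.tokenizer_ = WordPieceTokenizer.train(texts, vocab_size=enc.vocab_size)
        encoder = TransformerEncoder(
            vocab_size=self.tokenizer_.vocab_size,
            layers=enc.layers,
            hidden=enc.hidden_size,
            heads=enc.attention_heads,
            max_len=enc.max_sequence_length,
            rng=rng,
        )
        net = TokenTaggerNet(encoder, rng, n_labels=3, head_init_sd=tc.head_init_sd)

        encoded = [self._encode(t, enc, spans=s) for t, s in zip(texts, all_spans)]
        n = len(encoded)
        steps = math.ceil(n / tc.batch_size) * tc.epochs
        opt = Adam(net.params(),
                   LinearWarmupSchedule(tc.learning_rate, tc.warmup_steps, steps),
                   clip_norm=tc.clip_norm)
        pad = self.tokenizer_.pad_id()
        history = []
        for _ in range(tc.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for b0 in range(0, n, tc.batch_size):
                idx = order[b0 : b0 + tc.batch_size]
                ids, mask, labels, score_mask = _pad_tagged([encoded[i] for i in idx], pad)
                opt.zero_grad()
                logits = net(ids, np.zeros_like(ids), mask,
                             p_drop=tc.dropout, rng=rng)
                loss, _ = ag.softmax_cross_entropy(logits, labels, score_mask)
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            history.append(epoch_loss / n)

        self.encoder_ = enc
        self.training_ = tc
        self.net_ = net
        self.history_ = history
        return self

    def predict(self, X: Sequence[str]) -> list[list[tuple[int, int]]]:
        if not hasattr(self, "net_"):
            raise RuntimeError("tagger is not fitted")
        out: list[list[tuple[int, int]]] = []
        pad = self.tokenizer_.pad_id()
        for text in X:
            item = self._encode(text, self.encoder_)
            if not item["word_offsets"]:
                out.append([])
                continue
            ids, mask, _, _ = _pad_tagged([item], pad)
            logits = self.net_(ids, np.zeros_like(ids), mask).data[0]
            word_labels = [
                _LABEL_NAMES[int(np.argmax(logits[pos]))]
                for pos in item["first_piece_positions"]
            ]
            out.append(decode_bio(word_labels, item["word_offsets"]))
        return out

    def _encode(self, text: str, enc: EncoderConfig, spans=None) -> dict:
        toks = tokenize_with_offsets(text)
        word_labels = None
        if spans is not None:
            word_labels = [
                {"O": _O, "B": _B, "I": _I}[t.bio_label]
                for t in bio_encode(text, spans)
            ]
        ids = [self.tokenizer_.token_to_id[CLS]]
        labels = [_O]
        score = [0]
        first_positions: list[int] = []
        word_offsets: list[tuple[int, int]] = []
        budget = enc.max_sequence_length - 2
        for wi, (word, ts, te) in enumerate(toks):
            pieces = self.tokenizer_.tokenize_word(word.lower())
            if len(ids) - 1 + len(pieces) > budget:
                break
            first_positions.append(len(ids))
            word_offsets.append((ts, te))
            lab = word_labels[wi] if word_labels is not None else _O
            for j, p in enumerate(pieces):
                ids.append(self.tokenizer_.convert_tokens_to_ids([p])[0])
                labels.append(lab)
                score.append(1 if j == 0 else 0)
        ids.append(self.tokenizer_.token_to_id[SEP])
        labels.append(_O)
        score.append(0)
        return {
            "ids": np.array(ids, dtype=np.int64),
            "labels": np.array(labels, dtype=np.int64),
            "score": np.array(score, dtype=np.int64),
            "first_piece_positions": first_positions,
            "word_offsets": word_offsets,
        }


def _pad_tagged(items: Sequence[dict], pad_id: int):
    T = max(len(i["ids"]) for i in items)
    B = len(items)
    ids = np.full((B, T), pad_id, dtype=np.int64)
    mask = np.zeros((B, T), dtype=np.int64)
    labels = np.zeros((B, T), dtype=np.int64)
    score = np.zeros((B, T), dtype=np.int64)
    for r, it in enumerate(items):
        L = len(it["ids"])
        ids[r, :L] = it["ids"]
        mask[r, :L] = 1
        labels[r, :L] = it["labels"]
        score[r, :L] = it["score"]
    return ids, mask, labels, score


def train_tagger(docs: Sequence[str], spans: Sequence[Sequence[tuple[int, int]]],
                 enc: Optional[EncoderConfig] = None,
                 tc: Optional[TrainingConfig] = None) -> BioSpanTagger:
    return BioSpanTagger(encoder=enc, training=tc).fit(docs, spans)


def predict_spans(model: BioSpanTagger, doc: str) -> list[tuple[int, int]]:
    return model.predict([doc])[0]


def evaluate_ner(pred_spans: Sequence[tuple[int, int]],
                 gold_spans: Sequence[tuple[int, int]]) -> ConfusionCounts:
    """Exact span matching for one document (multiset one-to-one)."""
    gold_left = [tuple(g) for g in gold_spans]
    preds = [tuple(p) for p in pred_spans]
    tp = 0
    for s in preds:
        if s in gold_left:
            gold_left.remove(s)
            tp += 1
    return ConfusionCounts(tp, len(preds) - tp, len(gold_left))


def code_and_evaluate(
    pred_spans_by_doc: dict[str, Sequence[tuple[int, int]]],
    texts_by_doc: dict[str, str],
    lexicon: Lexicon,
    gold_by_doc: dict[str, GoldLabeling],
    flt: SemanticTypeFilter | None = None,
) -> ConfusionCounts:
    """CUI-level end-to-end scoring of extracted spans.

    Each extracted phrase is coded with :func:`code_phrase` (uncodable
    phrases are dropped); per document, the deduplicated predicted CUI set
    is compared against the gold CUI set.
    """
    total = ConfusionCounts(0, 0, 0)
    for doc_id, gold in gold_by_doc.items():
        text = texts_by_doc[doc_id]
        pred_cuis = set()
        for s, e in pred_spans_by_doc.get(doc_id, ()):
            cui = code_phrase(text[s:e], lexicon, flt)
            if cui is not None:
                pred_cuis.add(cui)
        g = set(gold.gold_cuis)
        total = total + ConfusionCounts(
            tp=len(pred_cuis & g), fp=len(pred_cuis - g), fn=len(g - pred_cuis)
        )
    return total


@dataclass
class BaselineReport:
    """Grouped-CV results of the baseline: exact-span and coded scoring."""

    runs: int
    k: int
    fold_metrics_ner: list[list[Metrics]]
    fold_metrics_coded: list[list[Metrics]]

    def _agg(self, per_run):
        run_means = np.array(
            [[np.mean([f.precision for f in run]),
              np.mean([f.recall for f in run]),
              np.mean([f.f1 for f in run])] for run in per_run])
        return (Metrics(*map(float, run_means.mean(axis=0))),
                Metrics(*map(float, run_means.std(axis=0))))

    @property
    def ner_mean(self) -> Metrics:
        return self._agg(self.fold_metrics_ner)[0]

    @property
    def ner_sd(self) -> Metrics:
        return self._agg(self.fold_metrics_ner)[1]

    @property
    def coded_mean(self) -> Metrics:
        return self._agg(self.fold_metrics_coded)[0]

    @property
    def coded_sd(self) -> Metrics:
        return self._agg(self.fold_metrics_coded)[1]


def cross_validate_tagger(
    texts_by_doc: dict[str, str],
    spans_by_doc: dict[str, Sequence[tuple[int, int]]],
    gold_by_doc: dict[str, GoldLabeling],
    lexicon: Lexicon,
    make_tagger: Callable[[int], BioSpanTagger],
    runs: int = 10,
    k: int = 5,
    seed: int = 0,
    flt: SemanticTypeFilter | None = None,
) -> BaselineReport:
    """Repeated document-grouped k-fold CV of the BIO baseline."""
    from .evaluation import grouped_folds

    doc_ids = sorted(texts_by_doc)
    fm_ner: list[list[Metrics]] = []
    fm_coded: list[list[Metrics]] = []
    for run in range(runs):
        run_seed = seed + 1000 * run
        assignment = grouped_folds(doc_ids, k=k, seed=run_seed)
        row_ner, row_coded = [], []
        for fold in range(k):
            test_docs = [d for d in doc_ids if assignment[d] == fold]
            train_docs = [d for d in doc_ids if assignment[d] != fold]
            tagger = clone(make_tagger(run_seed + fold))
            tagger.fit([texts_by_doc[d] for d in train_docs],
                       [spans_by_doc[d] for d in train_docs])
            preds = tagger.predict([texts_by_doc[d] for d in test_docs])
            counts = ConfusionCounts(0, 0, 0)
            for d, p in zip(test_docs, preds):
                counts = counts + evaluate_ner(p, spans_by_doc[d])
            row_ner.append(prf(counts))
            coded = code_and_evaluate(
                dict(zip(test_docs, preds)),
                {d: texts_by_doc[d] for d in test_docs},
                lexicon,
                {d: gold_by_doc[d] for d in test_docs},
                flt,
            )
            row_coded.append(prf(coded))
        fm_ner.append(row_ner)
        fm_coded.append(row_coded)
    return BaselineReport(runs=runs, k=k, fold_metrics_ner=fm_ner,
                          fold_metrics_coded=fm_coded)
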