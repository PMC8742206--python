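"""Transformer encoder and task heads built on the autograd core.

The encoder follows the standard bidirectional-transformer recipe: summed
token/segment/position embeddings with layer normalization, a stack of
post-norm encoder blocks (multi-head self-attention and a GELU feed-forward
sublayer, residual connections, layer norm), and task heads on top — a
2-way classification head over the pooled [CLS] state, or a per-token head
for BIO tagging.  All weights are initialized from a truncated normal with
mean 0 and SD 0.02; layer-norm gains start at 1 and biases at 0.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["trunc_normal", "TransformerEncoder", "SequenceClassifierNet", "TokenTaggerNet"]


def trunc_normal(
    rng: np.random.Generator, shape: tuple, sd: float = 0.02
) -> np.ndarray:
    """Truncated normal (mean 0, clipped to ±2 SD by resampling)."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > 2 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > 2 * sd
    return out


def _param(rng, shape, sd=0.02) -> Tensor:
    return Tensor(trunc_normal(rng, shape, sd))


def _width_sd(hidden: int) -> float:
    """Weight-init SD scaled to the encoder width.

    The canonical 0.02 was chosen for hidden size 768; narrower encoders
    use 0.02 * sqrt(768 / hidden) so activations start at a comparable
    scale regardless of the preset.
    """
    return 0.02 * float(np.sqrt(768.0 / hidden))


def alibi_slopes(heads: int) -> np.ndarray:
    """Geometric per-head slopes for the relative-distance attention bias."""
    return np.array([2.0 ** (-8.0 * (i + 1) / heads) for i in range(heads)])


class _Block:
    """One post-norm encoder layer.

    Attention scores carry a fixed per-head relative-distance penalty
    (slope * -|i - j|) in addition to the learned absolute position
    embeddings.  A pretrained encoder arrives with local attention heads
    already formed; training from scratch on a small corpus does not, so
    this bias supplies the locality prior directly — without it the
    network cannot discover that the tokens surrounding an anchor marker
    are the ones that matter.
    """

    def __init__(self, hidden: int, heads: int, rng: np.random.Generator):
        if hidden % heads:
            raise ValueError("hidden_size must be divisible by attention_heads")
        self.hidden, self.heads = hidden, heads
        self.dh = hidden // heads
        ff = 4 * hidden
        sd = _width_sd(hidden)
        self.wq, self.wk, self.wv, self.wo = (_param(rng, (hidden, hidden), sd) for _ in range(4))
        self.bq, self.bk, self.bv, self.bo = (Tensor(np.zeros(hidden)) for _ in range(4))
        self.ln1_g, self.ln1_b = Tensor(np.ones(hidden)), Tensor(np.zeros(hidden))
        self.w1, self.b1 = _param(rng, (hidden, ff), sd), Tensor(np.zeros(ff))
        self.w2, self.b2 = _param(rng, (ff, hidden), sd), Tensor(np.zeros(hidden))
        self.ln2_g, self.ln2_b = Tensor(np.ones(hidden)), Tensor(np.zeros(hidden))

    def params(self) -> list[Tensor]:
        return [
            self.wq, self.bq, self.wk, self.bk, self.wv, self.bv, self.wo, self.bo,
            self.ln1_g, self.ln1_b, self.w1, self.b1, self.w2, self.b2,
            self.ln2_g, self.ln2_b,
        ]

    def __call__(self, x: Tensor, attn_bias: np.ndarray, p_drop: float, rng) -> Tensor:
        B, T, H = x.shape
        nh, dh = self.heads, self.dh

        def split(t: Tensor) -> Tensor:
            return ag.transpose(ag.reshape(t, (B, T, nh, dh)), (0, 2, 1, 3))

        q = split(ag.add(ag.matmul(x, self.wq), self.bq))
        k = split(ag.add(ag.matmul(x, self.wk), self.bk))
        v = split(ag.add(ag.matmul(x, self.wv), self.bv))
        scores = ag.mul(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        att = ag.softmax(scores, bias=attn_bias)
        att = ag.dropout(att, p_drop, rng)
        ctx = ag.reshape(ag.transpose(ag.matmul(att, v), (0, 2, 1, 3)), (B, T, H))
        ctx = ag.dropout(ag.add(ag.matmul(ctx, self.wo), self.bo), p_drop, rng)
        x = ag.layer_norm(ag.add(x, ctx), self.ln1_g, self.ln1_b)

        h = ag.gelu(ag.add(ag.matmul(x, self.w1), self.b1))
        h = ag.dropout(ag.add(ag.matmul(h, self.w2), self.b2), p_drop, rng)
        return ag.layer_norm(ag.add(x, h), self.ln2_g, self.ln2_b)


class TransformerEncoder:
    """Embeddings + stacked encoder blocks; returns (B, T, H) hidden states."""

    def __init__(
        self,
        vocab_size: int,
        layers: int,
        hidden: int,
        heads: int,
        max_len: int,
        rng: np.random.Generator,
        n_segments: int = 2,
    ):
        self.vocab_size, self.max_len, self.hidden = vocab_size, max_len, hidden
        sd = _width_sd(hidden)
        self.tok_emb = _param(rng, (vocab_size, hidden), sd)
        self.seg_emb = _param(rng, (n_segments, hidden), sd)
        self.pos_emb = _param(rng, (max_len, hidden), sd)
        self.emb_ln_g, self.emb_ln_b = Tensor(np.ones(hidden)), Tensor(np.zeros(hidden))
        self._slopes = alibi_slopes(heads)
        self.blocks = [_Block(hidden, heads, rng) for _ in range(layers)]

    def params(self) -> list[Tensor]:
        out = [self.tok_emb, self.seg_emb, self.pos_emb, self.emb_ln_g, self.emb_ln_b]
        for b in self.blocks:
            out.extend(b.params())
        return out

    def __call__(
        self,
        token_ids: np.ndarray,
        segment_ids: np.ndarray,
        attention_mask: np.ndarray,
        p_drop: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        B, T = token_ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        pos_ids = np.broadcast_to(np.arange(T), (B, T))
        x = ag.add(
            ag.add(ag.embedding(self.tok_emb, token_ids), ag.embedding(self.seg_emb, segment_ids)),
            ag.embedding(self.pos_emb, pos_ids),
        )
        x = ag.layer_norm(x, self.emb_ln_g, self.emb_ln_b)
        x = ag.dropout(x, p_drop, rng)
        # additive attention bias: -1e9 for padding keys plus the fixed
        # per-head relative-distance penalty
        pad_bias = np.where(attention_mask[:, None, None, :] > 0, 0.0, -1e9)
        pos = np.arange(T)
        dist = np.abs(pos[:, None] - pos[None, :])
        rel = -self._slopes[:, None, None] * dist
        bias = (pad_bias + rel[None, :, :, :]).astype(ag.DTYPE)
        for block in self.blocks:
            x = block(x, bias, p_drop, rng)
        return x


class SequenceClassifierNet:
    """Encoder + dropout + 2-way head over the pooled [CLS] output."""

    def __init__(self, encoder: TransformerEncoder, rng, n_classes: int = 2,
                 head_init_sd: float = 0.02):
        self.encoder = encoder
        self.head_w = _param(rng, (encoder.hidden, n_classes), sd=head_init_sd)
        self.head_b = Tensor(np.zeros(n_classes))

    def params(self) -> list[Tensor]:
        return self.encoder.params() + [self.head_w, self.head_b]

    def __call__(self, token_ids, segment_ids, attention_mask,
                 p_drop: float = 0.0, rng=None) -> Tensor:
        h = self.encoder(token_ids, segment_ids, attention_mask, p_drop, rng)
        pooled = ag.dropout(ag.select_first(h), p_drop, rng)
        return ag.add(ag.matmul(pooled, self.head_w), self.head_b)


class TokenTaggerNet:
    """Encoder + dropout + per-token head (BIO tagging)."""

    def __init__(self, encoder: TransformerEncoder, rng, n_labels: int = 3,
                 head_init_sd: float = 0.02):
        self.encoder = encoder
        self.head_w = _param(rng, (encoder.hidden, n_labels), sd=head_init_sd)
        self.head_b = Tensor(np.zeros(n_labels))

    def params(self) -> list[Tensor]:
        return self.encoder.params() + [self.head_w, self.head_b]

    def __call__(self, token_ids, segment_ids, attention_mask,
                 p_drop: float = 0.0, rng=None) -> Tensor:
        h = self.encoder(token_ids, segment_ids, attention_mask, p_drop, rng)
        h = ag.dropout(h, p_drop, rng)
        return ag.add(ag.matmul(h, self.head_w), self.head_b)
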