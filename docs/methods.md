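# Methods

## Problem setting

An SAE narrative is a short free-text clinical note (here, a mean of ~37
tokens). The coding task maps each document to the set of UMLS CUIs that
describe adverse events occurring *now or in the recent past* — historical
conditions, negated findings and hypothetical events do not count. The
pipeline separates *finding* candidate concepts (dictionary lookup) from
*deciding* whether each candidate is an adverse event in its context
(binary classification), and is evaluated end to end at the CUI level.

## Dictionary lookup

The lexicon is a TSV inventory of (CUI, semantic type, term, preferred
flag) rows with exactly one preferred term per CUI. Lookup is greedy
leftmost-longest matching over surface tokens, case-insensitive, restricted
to six semantic types, with no stemming, lexical-variant generation or
word-sense disambiguation — it is an idealized, deterministic stand-in for
a MetaMap-style recognizer. Consequences embraced by the design:

- equal-length ties at one position resolve to the lexicographically lower
  CUI (determinism; the choice is otherwise arbitrary);
- a gold concept whose surface form is absent from the lexicon is never
  surfaced; the evaluation amalgamates such misses into the end-to-end
  false negatives rather than pretending the stage is perfect.

Offsets are 0-based half-open character spans over the *normalized* text;
the preprocessing stage keeps a monotone character map back to the raw
text so stand-off annotations can be projected either way.

## Preprocessing

Normalization lowercases, separates punctuation into standalone tokens,
expands a fixed list of English enclitics, and substitutes whole-token
abbreviations from a TSV table (the bundled default covers the synthetic
corpus and common clinical shorthand). Normalization is idempotent.
Sentence segmentation is rule-based (terminator tokens with a decimal and
honorific/initial guard) and is used only for generation and reporting —
the classifier always sees whole documents, because context beyond the
sentence (e.g. an admission clause earlier in the note) carries signal.

## Concept anchoring

One candidate instance per *distinct* CUI per document. In each copy,
every recognized mention of any CUI is replaced by its preferred name
(surface regularization), and every occurrence of the instance's own CUI
is wrapped in the reserved atomic tokens `[A] ... [/A]`. Anchoring gives
the classifier a uniform single-concept question regardless of how many
events a document mentions, and regularization removes surface variation
the classifier would otherwise have to learn. Gold labels are document
level CUI sets; a candidate is positive iff its CUI is in the set.

## Classifier

Input: `[CLS] concept [SEP] anchored-document [SEP]` with segment ids
0/1, WordPiece subword tokenization (vocabulary learned on the training
corpus; anchor markers atomic). Only the context segment is truncated,
from the right, and never into the first anchor region; with
`max_sequence_length = 256` (default) and ~40-token documents truncation
does not occur in practice.

Encoder: bidirectional transformer — summed token/segment/position
embeddings with layer norm, post-norm blocks of multi-head self-attention
and GELU feed-forward sublayers. Two presets share the interface:

| preset | layers | hidden | heads | init |
|---|---|---|---|---|
| tiny (default) | 2 | 64 | 4 | random, trained from scratch |
| base | 12 | 768 | 12 | checkpoint directory (`pretrained=`) |

Head: dropout 0.1 over the pooled `[CLS]` state, then a 2-way linear
layer initialized from a truncated normal (mean 0, SD 0.02); softmax
cross-entropy loss; Adam with clip norm 1.0 and linear warmup (100 steps)
with linear decay. `TrainingConfig` defaults are the published
fine-tuning values (2e-5, 8 epochs, batch 8).

### Training the tiny preset from scratch

Three adaptations make the 2-layer encoder trainable from random
initialization on a few hundred documents; all are encoder/training
implementation choices behind the same interface, and the base preset
with a checkpoint does not need them:

1. **Width-aware initialization.** The canonical SD 0.02 was chosen for
   hidden size 768; narrower encoders use `0.02 * sqrt(768 / hidden)` so
   activations start at a comparable scale (the head keeps SD 0.02).
2. **Relative-distance attention bias.** Each head adds a fixed penalty
   `-slope_h * |i - j|` to its attention scores (geometric slopes across
   heads). A pretrained encoder arrives with local heads already formed;
   from scratch, this locality prior is what lets the network discover
   that the tokens surrounding an anchor marker are the informative ones.
3. **Anchor-protected word dropout** (`word_dropout = 0.4` in the tiny
   training preset). During training, input tokens are replaced by
   `[UNK]` with probability 0.4, sparing special tokens and a ±3-token
   window around each anchor marker. Without it the dominant solution on
   a small corpus is to memorize document signatures — training loss goes
   to zero while held-out F1 stalls near the majority rate; corrupting
   everything except the anchor neighbourhood forces the network onto the
   anchor-adjacent cues that generalize. The desk-scale preset also uses
   learning rate 1e-3 and 24 epochs (2e-5 over 8 epochs is a fine-tuning
   schedule for a pretrained 110M-parameter encoder and cannot move a
   randomly initialized network appreciably).

The whole stack (autograd, encoder, optimizer) is numpy in float32,
single-threaded, gradient-checked against central finite differences in
float64. With one seed, repeated runs are bit-identical; evaluation
results are independent of batch composition because padded positions are
exactly masked out of attention.

Classification threshold is 0.5 on the positive-class probability; the
prediction-probability histogram concentrates near 0 and 1 on separable
data, so the threshold is not critical.

## BIO baseline

The comparison system reverses the stage order: the same encoder is
fine-tuned as a per-token B/I/O tagger of adverse-event phrases (subword
pieces inherit their word's label; only first pieces are scored), spans
are decoded with the repair rule *I after O or start → B*, and each
extracted phrase is coded with the lexicon's phrase-coding rule (exact
match, else longest contained term, else dropped). It is scored both by
exact span match and at the CUI level. Its characteristic failure is
boundary truncation: "tract infection" codes to the broader infection
concept, producing both a false positive and a false negative.

## Evaluation

Document-grouped k-fold cross-validation, repeated: documents (not
candidates) are shuffled and split, so all candidates of a document share
its fold; per run the metrics are averaged over the k folds, then mean and
SD are taken over runs. Classifier-only metrics score the surfaced
candidates; end-to-end metrics amalgamate lookup misses into FN, which
leaves precision unchanged and can only lower recall — the structural gap
between the two is a property of the pipeline order, not of the
classifier. ROC and PR curves and trapezoidal AUCs come from
scikit-learn behind the module surface (validated against a pairwise
concordance oracle in the tests); the no-skill references are the ROC
diagonal and the PR horizontal at positive prevalence.

## Inter-annotator agreement

Phrase annotation has no well-defined count of negative cases, so kappa
is undefined; agreement is measured with IR metrics by treating one
annotator as gold. Matching is one-to-one per document, by exact span by
default; an overlap mode (any positional intersection, greedy in span
order) exists because the matching criterion is genuinely open — the
bundled engineered fixture gives identical counts in both modes. F1 is
symmetric under swapping annotators; FP + FN is the adjudication queue.

## Synthetic corpus

The generator emulates the statistical shape of an annotated SAE corpus:
mean ~37 tokens per document, ~3.5 gold CUIs per document, ~66.2% of
surfaced candidates positive, and a 0.15 lookup-miss rate (planted as
paraphrases absent from the lexicon, e.g. *breathlessness* for dyspnea —
chosen so they contain no lexicon term at token boundaries). Documents
are assembled from templated clauses: positive frames ("admitted to
hospital with {c}", "patient experienced {c}"), negative frames split
0.4/0.4/0.2 over history ("known to have {c}"), negation ("no {c}") and
hypothetical ("monitor for {c}") contexts, plus concept-free openers and
fillers that set the length scale. The per-concept adverse-event
probability is derived from the target candidate prevalence and the miss
rate (q = f / (f + (1-m)(1-f))), and concepts per document from the label
target divided by q. A candidate's label is fully determined by its
frame, which is exactly the contextual signal the classifier is supposed
to learn — and exactly what templated text can and cannot show: passing
tests demonstrate that the pipeline machinery and the context-learning
mechanism work, not that the tiny model handles free clinical prose,
misspellings, or negation scope in the wild. The simulated second
annotator drops gold spans and adds spurious ones at rates matched to the
published agreement table (98/842 and 50/842); an engineered deterministic
pair reproduces the exact counts (744, 50, 98). The frozen hard cases
reproduce documented failure patterns (negation scope, *decreased
mobility* vs *decreased pain*, one concept in multiple contexts); the
suite reports accuracy on them without asserting it.

Uniform trial assignment is used; the per-trial document-count skew of
real multi-trial corpora is not emulated.

## Desk-scale experiment sizes

The bundled experiments (acceptance script and test suite) use a
200-document corpus, single-run 5-fold grouped CV for each system, and a
286-document corpus for the prevalence estimate; these sizes give stable
means on one CPU in minutes. The candidate bookkeeping keeps one
consistent count (candidates = concepts the lookup surfaced; gold =
positives + planted misses) and the conservation identity
`positives + misses = gold labels` is asserted corpus-wide.

## Known limitations

- The lookup is idealized: no variant generation means its miss rate is
  entirely controlled by the lexicon; real MetaMap behaves differently.
- Negation and polarity are unmodelled by design (the hard cases document
  this); a context-rule pass such as a ConText-style algorithm would be
  the natural next stage.
- The tiny preset's from-scratch adaptations (locality bias, word
  dropout) are not needed by, and not applied to, a pretrained base
  encoder; conclusions about the base preset require such a checkpoint.
- Templated text cannot test robustness to real clinical language.
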