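# aecoder

Automated coding of adverse events (AEs) in the narrative sections of
serious-adverse-event (SAE) report forms.

Clinical-trial safety teams receive SAE narratives as free text. Signs and
symptoms mentioned there are only useful for safety-signal detection once
they are *coded* — mapped to concept unique identifiers (CUIs) of a
standard terminology such as the UMLS. The hard part is not finding
mentions of signs and symptoms but deciding which of them are adverse
events: the same concept can appear as an acute event ("admitted with
pleural effusion"), as medical history ("known to have pleural effusion"),
negated, or as a hypothetical, often within a single sentence.

`aecoder` implements a two-stage pipeline for this decision:

1. **Dictionary lookup.** A UMLS-like lexicon is matched against the
   normalized narrative (greedy leftmost-longest, token-boundary,
   case-insensitive), restricted to six semantic types: *disease or
   syndrome, finding, injury or poisoning, neoplastic process,
   pathological function, sign or symptom*. Every match is a candidate AE
   with a CUI.
2. **Concept-anchored classification.** For each distinct candidate CUI the
   document is copied, all recognized mentions are regularized to their
   preferred names, and every occurrence of the candidate is wrapped in
   anchor markers `[A] ... [/A]`. A binary transformer classifier reads the
   pair *(concept, anchored document)* as
   `[CLS] concept [SEP] document [SEP]` and answers one question: *given
   this context, does the anchored concept constitute an adverse event?*
   The pooled `[CLS]` state feeds a 2-way softmax head; training minimizes
   cross-entropy with Adam (learning rate 2e-5, batch 8, 8 epochs, clip
   norm 1.0, 100 warmup steps with linear decay, dropout 0.1) in the
   paper-faithful preset.

The document's predicted code set is the set of accepted candidate CUIs.
Gold AEs that the lookup never surfaced are *amalgamated* into the false
negatives of the end-to-end system, so evaluation never hides dictionary
misses. Scoring uses precision, recall and F1 (`P = TP/(TP+FP)`,
`R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`) under repeated document-grouped
k-fold cross-validation.

The package also contains:

- the competing **extract-then-code baseline**: the same encoder fine-tuned
  for BIO span tagging, with extracted phrases coded against the lexicon
  afterwards (a truncated extraction like "tract infection" degrades to the
  broader "infection" concept — one FP plus one FN);
- **inter-annotator agreement** tooling over BRAT stand-off annotations
  using the same IR metrics (F1 is symmetric under swapping annotators, so
  it serves as an agreement measure where kappa is undefined);
- a seeded **synthetic SAE corpus generator** (templated clinical clauses,
  planted lookup misses, a simulated second annotator, frozen hard cases
  for negation and polarity errors) so the whole pipeline runs without any
  confidential data;
- a numpy transformer encoder with its own reverse-mode autograd,
  WordPiece-style tokenizer and Adam/warmup training loop, so nothing
  beyond the scientific Python stack is required.

Everything is exposed both as a library of sklearn-style estimators
(`AnchoredConceptClassifier`, `BioSpanTagger` — `fit`/`predict_proba`,
`get_params`, clonable) and as an `aecoder` command line with
`generate | lookup | anchor | train | predict | evaluate | baseline | agree`
subcommands.

## Worked example

```python
from aecoder import (normalize, default_abbreviations, toy_lexicon,
                     find_concept_mentions, make_candidates)

lex = toy_lexicon()
doc = normalize("Pt admitted with lower respiratory tract infection and SOB.",
                default_abbreviations(), doc_id="d1")
print(doc.normalized_text)
for m in find_concept_mentions(doc.normalized_text, lex):
    print(m.cui, m.matched_text)
for c in make_candidates(doc, find_concept_mentions(doc.normalized_text, lex), lex):
    print(c.cui, "|", c.anchored_text)
```

prints

```
patient admitted with lower respiratory tract infection and shortness of breath .
C0035243 respiratory tract infection
C0013404 shortness of breath
C0013404 | patient admitted with lower respiratory tract infection and [A] dyspnea [/A] .
C0035243 | patient admitted with lower [A] respiratory tract infection [/A] and dyspnea .
```

Note what the anchoring stage did: abbreviations were expanded (`Pt`,
`SOB`), the longest phrase won over its sub-phrase (`respiratory tract
infection`, not `infection`), each candidate got its own document copy with
its occurrences anchored, and the synonym `shortness of breath` was
regularized to the preferred name `dyspnea`.

Agreement between two annotation sets, on the bundled engineered fixture
(two simulated annotators over a synthetic corpus):

```sh
aecoder generate --n 18 --seed 3 --out corpus/   # or any .ann directories
aecoder agree --ann-a annA/ --ann-b annB/
```

prints, for the engineered pair,

```
TP=744 FP=50 FN=98
P=0.9370 R=0.8836 F1=0.9095
disagreements=148
```

meaning: 744 spans matched one-to-one, annotator B marked 50 spans A did
not, A marked 98 that B missed, and the 148 disagreements would go to
adjudication. The F1 of 0.9095 is the human agreement ceiling against
which the system is judged.

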