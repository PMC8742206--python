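# File formats

All artifacts are plain text (UTF-8).

## Corpus (JSONL)

One document per line:

```json
{"doc_id": "doc-0001", "text": "patient admitted with ..."}
```

Plain `.txt` files (one document per file, file stem = doc_id) are
accepted wherever a corpus is read programmatically.

## Lexicon (TSV)

Header required, four tab-separated columns:

```
cui	semantic_type	term	preferred
C0035243	disease or syndrome	respiratory tract infection	1
```

- `cui` matches `^C[0-9]{7}$`
- `semantic_type` is one of: disease or syndrome, finding, injury or
  poisoning, neoplastic process, pathological function, sign or symptom
- `preferred` is 0 or 1; exactly one preferred term per CUI
- duplicate (term, cui) rows are deduplicated on load

## Abbreviation table (TSV)

```
short	long
sob	shortness of breath
```

Keys are unique case-insensitively; no key may map to itself.

## Stand-off annotations (BRAT dialect, .ann)

One file per document (file stem = doc_id). Entity lines, optionally
followed by UMLS normalization lines:

```
T1	AdverseEvent 28 55	respiratory tract infection
N1	Reference T1 UMLS:C0035243	respiratory tract infection
```

Offsets are 0-based half-open character positions into the document text;
the annotation text must equal the document slice.

## Candidate instances (JSONL)

```json
{"doc_id": "doc-0001", "cui": "C0032227", "concept_text": "pleural effusion",
 "anchored_text": "... [A] pleural effusion [/A] ...", "label": "positive"}
```

`label` is `positive`, `negative` or `unknown`.

## Predictions (JSONL)

```json
{"doc_id": "doc-0001", "cui": "C0032227", "prob_positive": 0.97,
 "label": "positive"}
```

## Model checkpoint (directory)

- `config.json` — encoder and training configuration snapshot
- `vocab.json` — WordPiece vocabulary (JSON list, index = token id)
- `weights.npz` — parameter arrays `p0 ... pN` in `net.params()` order

## Evaluation report (JSON)

`classifier_only` and `end_to_end` blocks with `mean`/`sd` of
precision/recall/F1, `auc_roc`, `auc_pr`, `positive_prevalence`,
`no_skill` references.

## Run manifest (manifest.json)

Written next to every CLI output: the subcommand, package version and the
effective configuration (including seeds). A run is reproducible from its
manifest alone.
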