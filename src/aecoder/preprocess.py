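"""Linguistic preprocessing of SAE narratives.

Normalization lowercases the text, separates punctuation into standalone
tokens, expands a fixed list of English enclitics (``can't`` -> ``cannot``)
and replaces whole-token abbreviations with their long forms from a
table (``sob`` -> ``shortness of breath``).  A per-character offset map from
the normalized text back to the raw text is kept so that any normalized
span can be projected onto the original document, as stand-off annotation
requires.  Sentence segmentation is rule-based with a decimal guard
(``38.5`` never splits) and is used for template generation and reporting
only — the classifier consumes whole documents.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ._tokens import tokenize_with_offsets

__all__ = [
    "Document",
    "AbbreviationTable",
    "load_abbreviations",
    "normalize",
    "segment",
]

# Fixed enclitic expansions; suffix rules handle the productive cases.
_ENCLITICS = {
    "can't": "cannot",
    "won't": "will not",
    "shan't": "shall not",
    "let's": "let us",
    "i'm": "i am",
}
_SUFFIX_RULES = [
    ("n't", " not"),
    ("'re", " are"),
    ("'ve", " have"),
    ("'ll", " will"),
]


@dataclass
class AbbreviationTable:
    """Whole-token short-form -> long-form substitutions."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lowered: dict[str, str] = {}
        for short, long in self.entries.items():
            key = short.lower()
            if key in lowered:
                raise ValueError(f"duplicate abbreviation (case-insensitive): {short!r}")
            if key == long.lower():
                raise ValueError(f"abbreviation {short!r} maps to itself")
            lowered[key] = long.lower()
        self.entries = lowered

    def get(self, token: str) -> Optional[str]:
        return self.entries.get(token.lower())


def load_abbreviations(path: str | Path) -> AbbreviationTable:
    """Load an abbreviation table from TSV (columns: short, long)."""
    entries: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != ["short", "long"]:
            raise ValueError("abbreviation TSV must have header: short<TAB>long")
        for row in reader:
            if not row or not row[0].strip():
                continue
            if len(row) != 2:
                raise ValueError(f"expected 2 fields, got {row!r}")
            entries[row[0].strip()] = row[1].strip()
    return AbbreviationTable(entries)


@dataclass
class Document:
    """A narrative with its normalized form and a normalized->raw offset map.

    ``char_raw_start[i]``/``char_raw_end[i]`` give the raw-text region that
    produced normalized character ``i``; both arrays are monotone
    non-decreasing, so span projection is simple index arithmetic.
    """

    doc_id: str
    raw_text: str
    normalized_text: str
    char_raw_start: list[int]
    char_raw_end: list[int]

    def project_span(self, start: int, end: int) -> tuple[int, int]:
        """Project a normalized [start, end) span onto the raw text."""
        if not (0 <= start < end <= len(self.normalized_text)):
            raise ValueError(f"span [{start}, {end}) out of bounds")
        return self.char_raw_start[start], self.char_raw_end[end - 1]


def _expand_token(token: str, table: AbbreviationTable | None) -> str:
    low = token.lower()
    if low in _ENCLITICS:
        return _ENCLITICS[low]
    for suffix, repl in _SUFFIX_RULES:
        if low.endswith(suffix) and len(low) > len(suffix):
            return low[: -len(suffix)] + repl
    if table is not None:
        long = table.get(low)
        if long is not None:
            return long
    return low


def normalize(
    raw_text: str,
    table: AbbreviationTable | None = None,
    doc_id: str = "",
) -> Document:
    """Normalize *raw_text*, keeping a character-level offset map.

    Output tokens are joined by single spaces; a separator character maps
    to the end of the preceding raw token so the map stays monotone.
    Unknown tokens pass through unchanged (lowercased).
    """
    out_parts: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for token, t_start, t_end in tokenize_with_offsets(raw_text):
        expanded = _expand_token(token, table)
        if out_parts:
            out_parts.append(" ")
            starts.append(ends[-1])
            ends.append(ends[-1])
        out_parts.append(expanded)
        starts.extend([t_start] * len(expanded))
        ends.extend([t_end] * len(expanded))
    normalized = "".join(out_parts)
    return Document(
        doc_id=doc_id,
        raw_text=raw_text,
        normalized_text=normalized,
        char_raw_start=starts,
        char_raw_end=ends,
    )


# Honorifics and similar truncations after which a period does not end a
# sentence; single-letter tokens (initials) are guarded generically.
_NO_BREAK_BEFORE_PERIOD = {"dr", "mr", "mrs", "ms", "prof", "st", "vs"}
_TERMINATORS = {".", "!", "?"}


def segment(normalized_text: str) -> list[tuple[int, int]]:
    """Split normalized text into sentence spans (char offsets, half-open).

    Spans cover the non-whitespace content in order; a standalone
    terminator token closes a sentence unless it follows an
    abbreviation-like token.  Decimals never split because the tokenizer
    keeps them whole.
    """
    toks = tokenize_with_offsets(normalized_text)
    if not toks:
        return []
    spans: list[tuple[int, int]] = []
    sent_start: Optional[int] = None
    prev_word = ""
    for i, (tok, start, end) in enumerate(toks):
        if sent_start is None:
            sent_start = start
        if tok in _TERMINATORS:
            guarded = tok == "." and (
                prev_word in _NO_BREAK_BEFORE_PERIOD or len(prev_word) == 1
            )
            if not guarded:
                spans.append((sent_start, end))
                sent_start = None
        prev_word = tok
    if sent_start is not None:
        spans.append((sent_start, toks[-1][2]))
    return spans
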