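"""Shared surface tokenization used by normalization, lookup and span handling.

A single token pattern is used everywhere so that token boundaries agree
between the preprocessing, dictionary-lookup and tagging stages:

* decimal numbers stay intact (``38.5`` is one token),
* words may carry internal apostrophes (``can't``) so enclitic expansion
  can see them whole,
* every other non-space character is its own token.
"""

from __future__ import annotations

import re

TOKEN_RE = re.compile(r"\d+\.\d+|\w+(?:'\w+)*|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Split *text* into surface tokens."""
    return TOKEN_RE.findall(text)


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Split *text* into ``(token, start, end)`` triples (0-based, half-open)."""
    return [(m.group(0), m.start(), m.end()) for m in TOKEN_RE.finditer(text)]
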