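"""UMLS-like lexicon and dictionary-based concept recognition.

The lexicon maps surface terms to concept unique identifiers (CUIs, the
``C`` + 7 digits codes of the UMLS Metathesaurus) together with a coarse
semantic type.  Candidate adverse-event mentions are found by greedy
leftmost-longest dictionary matching restricted to six semantic types, the
idealized stand-in for a MetaMap-style concept recognizer: matching is
case-insensitive, anchored at token boundaries, and returns non-overlapping
mentions.  No word-sense disambiguation or lexical-variant generation is
attempted; gold concepts whose surface form is absent from the lexicon are
simply never surfaced (the evaluation stage scores them as false negatives).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from ._tokens import tokenize, tokenize_with_offsets

__all__ = [
    "SEMANTIC_TYPES",
    "LexiconEntry",
    "SemanticTypeFilter",
    "ConceptMention",
    "Lexicon",
    "LexiconError",
    "LexiconParseError",
    "load_lexicon",
    "find_concept_mentions",
    "code_phrase",
]

#: The six UMLS semantic types admitted by the pipeline.
SEMANTIC_TYPES = frozenset(
    {
        "disease or syndrome",
        "finding",
        "injury or poisoning",
        "neoplastic process",
        "pathological function",
        "sign or symptom",
    }
)

_CUI_RE = re.compile(r"^C[0-9]{7}$")


class LexiconError(ValueError):
    """Invalid lexicon content (bad CUI, preferred-term violation, ...)."""


class LexiconParseError(LexiconError):
    """Malformed lexicon file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class LexiconEntry:
    """One (term, CUI) row of the lexicon."""

    cui: str
    term: str
    semantic_type: str
    preferred: bool = False


@dataclass(frozen=True)
class SemanticTypeFilter:
    """Restricts lookup to a set of semantic types (default: the six above)."""

    allowed: frozenset = SEMANTIC_TYPES

    def __contains__(self, semantic_type: str) -> bool:
        return semantic_type in self.allowed

    def without(self, semantic_type: str) -> "SemanticTypeFilter":
        return SemanticTypeFilter(self.allowed - {semantic_type})


@dataclass(frozen=True)
class ConceptMention:
    """A located, coded concept occurrence (0-based half-open char offsets)."""

    cui: str
    start: int
    end: int
    matched_text: str
    semantic_type: str


class Lexicon:
    """Term inventory indexed for leftmost-longest token-boundary lookup."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = []
        seen: set[tuple[str, str]] = set()
        for e in entries:
            if not _CUI_RE.match(e.cui):
                raise LexiconError(f"invalid CUI {e.cui!r} (expected C + 7 digits)")
            term = " ".join(tokenize(e.term.lower()))
            if not term:
                raise LexiconError(f"empty term for CUI {e.cui}")
            if e.semantic_type not in SEMANTIC_TYPES:
                raise LexiconError(
                    f"unknown semantic type {e.semantic_type!r} for CUI {e.cui}"
                )
            key = (term, e.cui)
            if key in seen:
                continue  # duplicate (term, cui) rows are deduplicated
            seen.add(key)
            self.entries.append(
                LexiconEntry(e.cui, term, e.semantic_type, e.preferred)
            )

        # exactly one preferred term per CUI
        pref: dict[str, list[str]] = {}
        for e in self.entries:
            if e.preferred:
                pref.setdefault(e.cui, []).append(e.term)
        for e in self.entries:
            n = len(pref.get(e.cui, []))
            if n != 1:
                raise LexiconError(
                    f"CUI {e.cui} has {n} preferred terms (exactly 1 required)"
                )
        self._preferred = {cui: terms[0] for cui, terms in pref.items()}
        self._semtype = {e.cui: e.semantic_type for e in self.entries}

        # token-tuple index; entry lists sorted by CUI for deterministic ties
        self._index: dict[tuple[str, ...], list[LexiconEntry]] = {}
        for e in self.entries:
            self._index.setdefault(tuple(e.term.split()), []).append(e)
        for bucket in self._index.values():
            bucket.sort(key=lambda e: e.cui)
        self._max_term_tokens = max(
            (len(k) for k in self._index), default=0
        )

    @property
    def cuis(self) -> set[str]:
        return set(self._preferred)

    def __len__(self) -> int:
        return len(self._preferred)

    def __contains__(self, cui: str) -> bool:
        return cui in self._preferred

    def preferred_name(self, cui: str) -> str:
        return self._preferred[cui]

    def semantic_type(self, cui: str) -> str:
        return self._semtype[cui]

    def lookup_tokens(
        self, tokens: tuple[str, ...], flt: SemanticTypeFilter
    ) -> Optional[LexiconEntry]:
        """Best eligible entry whose term equals *tokens*, or None.

        Ties between equally long entries resolve to the lexicographically
        lowest CUI (the buckets are pre-sorted).
        """
        for e in self._index.get(tokens, ()):
            if e.semantic_type in flt:
                return e
        return None


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from TSV (columns: cui, semantic_type, term, preferred)."""
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconParseError("missing header row", 1) from None
        expected = ["cui", "semantic_type", "term", "preferred"]
        if [h.strip().lower() for h in header] != expected:
            raise LexiconParseError(
                f"header must be {expected}, got {header}", 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise LexiconParseError(
                    f"expected 4 tab-separated fields, got {len(row)}", lineno
                )
            cui, semtype, term, preferred = (f.strip() for f in row)
            if preferred not in {"0", "1"}:
                raise LexiconParseError(
                    f"preferred flag must be 0 or 1, got {preferred!r}", lineno
                )
            try:
                entries.append(
                    LexiconEntry(cui, term, semtype.lower(), preferred == "1")
                )
            except LexiconError as exc:  # pragma: no cover - defensive
                raise LexiconParseError(str(exc), lineno) from exc
    return Lexicon(entries)


def find_concept_mentions(
    text: str,
    lexicon: Lexicon,
    flt: SemanticTypeFilter | None = None,
) -> list[ConceptMention]:
    """Greedy leftmost-longest dictionary matching over normalized text.

    Scans token positions left to right; at each position the longest
    eligible lexicon term starting there wins and the scan resumes after it,
    so the returned mentions never overlap.  Equal-length ties resolve to
    the lowest CUI.
    """
    flt = flt or SemanticTypeFilter()
    toks = tokenize_with_offsets(text.lower())
    words = [t[0] for t in toks]
    mentions: list[ConceptMention] = []
    i = 0
    n = len(words)
    max_len = lexicon._max_term_tokens
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            entry = lexicon.lookup_tokens(tuple(words[i : i + length]), flt)
            if entry is not None:
                hit = (entry, length)
                break
        if hit is None:
            i += 1
            continue
        entry, length = hit
        start = toks[i][1]
        end = toks[i + length - 1][2]
        mentions.append(
            ConceptMention(
                cui=entry.cui,
                start=start,
                end=end,
                matched_text=text[start:end],
                semantic_type=entry.semantic_type,
            )
        )
        i += length
    return mentions


def code_phrase(
    phrase: str,
    lexicon: Lexicon,
    flt: SemanticTypeFilter | None = None,
) -> Optional[str]:
    """Code a free-text phrase against the lexicon.

    An exact full-phrase match wins; otherwise the longest eligible lexicon
    term contained in the phrase at token boundaries is used (the closest
    concept), so a truncated extraction like ``tract infection`` degrades to
    the broader ``infection``.  Returns None when nothing in the phrase is
    in the lexicon.
    """
    if not phrase.strip():
        raise ValueError("phrase must be non-empty")
    flt = flt or SemanticTypeFilter()
    words = tuple(tokenize(phrase.lower()))
    exact = lexicon.lookup_tokens(words, flt)
    if exact is not None:
        return exact.cui
    # longest contained term wins; leftmost, then lowest CUI, on ties
    n = len(words)
    for length in range(min(lexicon._max_term_tokens, n), 0, -1):
        for i in range(n - length + 1):
            entry = lexicon.lookup_tokens(words[i : i + length], flt)
            if entry is not None:
                return entry.cui
    return None
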