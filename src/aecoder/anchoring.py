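"""Concept anchoring: one candidate instance per distinct concept.

A document that mentions several candidate concepts is copied once per
distinct CUI.  In each copy, every recognized mention (of any CUI) is
replaced by its preferred name — regularizing surface variation — and every
occurrence of the copy's own CUI is additionally wrapped in reserved anchor
markers ``[A]`` ... ``[/A]``.  This gives a single binary classifier a
uniform question to answer: *given this context, is the anchored concept an
adverse event?*

Gold labels are document-level CUI sets (deduplicated), so a candidate is
positive iff its CUI was annotated as an adverse event somewhere in the
document.  Gold CUIs that the dictionary lookup never surfaced are returned
as *missed* and later amalgamated into the false negatives of the
end-to-end system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import ConceptMention, Lexicon
from .preprocess import Document

__all__ = [
    "ANCHOR_OPEN",
    "ANCHOR_CLOSE",
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LABEL_UNKNOWN",
    "CandidateInstance",
    "GoldLabeling",
    "make_candidates",
    "label_candidates",
    "write_candidates_jsonl",
    "read_candidates_jsonl",
]

ANCHOR_OPEN = "[A]"
ANCHOR_CLOSE = "[/A]"

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNKNOWN = "unknown"


@dataclass(frozen=True)
class CandidateInstance:
    """One (document, CUI) pair: the classifier's unit of work."""

    doc_id: str
    cui: str
    concept_text: str
    anchored_text: str
    label: str = LABEL_UNKNOWN


@dataclass(frozen=True)
class GoldLabeling:
    """Deduplicated set of CUIs annotated as adverse events in a document."""

    doc_id: str
    gold_cuis: frozenset

    def __init__(self, doc_id: str, gold_cuis: Iterable[str]):
        object.__setattr__(self, "doc_id", doc_id)
        object.__setattr__(self, "gold_cuis", frozenset(gold_cuis))


def make_candidates(
    doc: Document,
    mentions: Sequence[ConceptMention],
    lexicon: Lexicon,
) -> list[CandidateInstance]:
    """Build one anchored candidate per distinct CUI mentioned in *doc*.

    Mentions must be the non-overlapping output of the dictionary lookup on
    ``doc.normalized_text``.  A mention CUI missing from the lexicon breaks
    the pipeline contract and raises ``KeyError``.
    """
    mentions = sorted(mentions, key=lambda m: m.start)
    for a, b in zip(mentions, mentions[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping mentions at {a.start}-{a.end}/{b.start}-{b.end}")
    for m in mentions:
        if m.cui not in lexicon:
            raise KeyError(f"mention CUI {m.cui} not in lexicon")

    text = doc.normalized_text
    candidates: list[CandidateInstance] = []
    for target in sorted({m.cui for m in mentions}):
        parts: list[str] = []
        pos = 0
        for m in mentions:
            parts.append(text[pos : m.start])
            name = lexicon.preferred_name(m.cui)
            if m.cui == target:
                parts.append(f"{ANCHOR_OPEN} {name} {ANCHOR_CLOSE}")
            else:
                parts.append(name)
            pos = m.end
        parts.append(text[pos:])
        candidates.append(
            CandidateInstance(
                doc_id=doc.doc_id,
                cui=target,
                concept_text=lexicon.preferred_name(target),
                anchored_text="".join(parts),
            )
        )
    return candidates


def label_candidates(
    candidates: Sequence[CandidateInstance],
    gold: GoldLabeling,
) -> tuple[list[CandidateInstance], set[str]]:
    """Attach gold labels; return ``(labeled, missed_cuis)``.

    A candidate is positive iff its CUI is in the gold set; gold CUIs with
    no candidate (dictionary-lookup misses) are returned separately and are
    later scored as false negatives of the end-to-end system.
    """
    for c in candidates:
        if c.doc_id != gold.doc_id:
            raise ValueError(
                f"candidate doc_id {c.doc_id!r} != gold doc_id {gold.doc_id!r}"
            )
    labeled = [
        replace(c, label=LABEL_POSITIVE if c.cui in gold.gold_cuis else LABEL_NEGATIVE)
        for c in candidates
    ]
    missed = set(gold.gold_cuis) - {c.cui for c in candidates}
    return labeled, missed


def write_candidates_jsonl(
    candidates: Iterable[CandidateInstance], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for c in candidates:
            fh.write(
                json.dumps(
                    {
                        "doc_id": c.doc_id,
                        "cui": c.cui,
                        "concept_text": c.concept_text,
                        "anchored_text": c.anchored_text,
                        "label": c.label,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_candidates_jsonl(path: str | Path) -> list[CandidateInstance]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(CandidateInstance(**json.loads(line)))
    return out
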