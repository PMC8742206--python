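"""Glue from raw narratives to labeled candidate instances.

One call runs normalize -> dictionary lookup -> anchoring -> gold labeling
for a whole corpus, returning per-document candidates and the gold CUIs the
lookup failed to surface (the input to false-negative amalgamation).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .anchoring import CandidateInstance, GoldLabeling, label_candidates, make_candidates
from .lexicon import Lexicon, SemanticTypeFilter, find_concept_mentions
from .preprocess import AbbreviationTable, normalize

__all__ = ["prepare_documents", "load_corpus_jsonl"]


def prepare_documents(
    texts: dict[str, str],
    gold_labels: dict[str, GoldLabeling],
    lexicon: Lexicon,
    table: Optional[AbbreviationTable] = None,
    flt: Optional[SemanticTypeFilter] = None,
) -> tuple[dict[str, list[CandidateInstance]], dict[str, set]]:
    """Run the candidate pipeline; returns (candidates_by_doc, missed_by_doc)."""
    flt = flt or SemanticTypeFilter()
    candidates_by_doc: dict[str, list[CandidateInstance]] = {}
    missed_by_doc: dict[str, set] = {}
    for doc_id in sorted(texts):
        doc = normalize(texts[doc_id], table, doc_id=doc_id)
        mentions = find_concept_mentions(doc.normalized_text, lexicon, flt)
        cands = make_candidates(doc, mentions, lexicon)
        gold = gold_labels.get(doc_id, GoldLabeling(doc_id, ()))
        labeled, missed = label_candidates(cands, gold)
        candidates_by_doc[doc_id] = labeled
        missed_by_doc[doc_id] = missed
    return candidates_by_doc, missed_by_doc


def load_corpus_jsonl(path: str | Path) -> dict[str, str]:
    """Read ``{"doc_id": ..., "text": ...}`` JSON lines into a dict."""
    texts: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                texts[rec["doc_id"]] = rec["text"]
    return texts
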