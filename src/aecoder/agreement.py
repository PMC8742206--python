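"""Inter-annotator agreement via information-retrieval metrics.

Phrase annotation has no well-defined universe of negative cases, so
chance-corrected coefficients such as Cohen's kappa are not applicable.
Instead, one annotator's spans are treated as the gold standard and the
other's as predictions: matched pairs are true positives, unmatched
predictions false positives, unmatched gold false negatives.  Computed
this way, F1 is symmetric under swapping annotators (precision and recall
merely exchange), which makes it a proper agreement measure; the FP + FN
remainder is the list of disagreements queued for adjudication.

Annotations are read and written in the BRAT stand-off dialect::

    T1\tAdverseEvent 10 16\ttremor
    N1\tReference T1 UMLS:C0040822\ttremor

The matching criterion defaults to exact character spans; an overlap mode
(any positional intersection, greedy one-to-one in span order) is also
provided.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .evaluation import ConfusionCounts, Metrics, prf

__all__ = [
    "StandoffAnnotation",
    "read_ann",
    "write_ann",
    "compare",
    "agreement_metrics",
]


@dataclass(frozen=True)
class StandoffAnnotation:
    """One highlighted phrase: document, character span, text, optional CUI."""

    doc_id: str
    start: int
    end: int
    text: str
    cui: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_N_RE = re.compile(r"^N\d+\tReference (T\d+) UMLS:(C\d{7})\t.*$")


def read_ann(path: str | Path, doc_id: Optional[str] = None) -> list[StandoffAnnotation]:
    """Parse a BRAT ``.ann`` file (T entity lines + optional N normalizations)."""
    path = Path(path)
    doc_id = doc_id if doc_id is not None else path.stem
    spans: dict[str, tuple[int, int, str]] = {}
    cuis: dict[str, str] = {}
    order: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        m = _T_RE.match(line)
        if m:
            tid, _type, start, end, text = m.groups()
            spans[tid] = (int(start), int(end), text)
            order.append(tid)
            continue
        m = _N_RE.match(line)
        if m:
            cuis[m.group(1)] = m.group(2)
            continue
        raise ValueError(f"{path.name}: unparseable line: {line!r}")
    return [
        StandoffAnnotation(doc_id, s, e, text, cuis.get(tid))
        for tid, (s, e, text) in ((t, spans[t]) for t in order)
    ]


def write_ann(annotations: Sequence[StandoffAnnotation], path: str | Path) -> None:
    lines = []
    for i, a in enumerate(sorted(annotations, key=lambda a: (a.start, a.end)), 1):
        lines.append(f"T{i}\tAdverseEvent {a.start} {a.end}\t{a.text}")
        if a.cui:
            lines.append(f"N{i}\tReference T{i} UMLS:{a.cui}\t{a.text}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def _validate_against_documents(
    annotations: Iterable[StandoffAnnotation], documents: dict[str, str]
) -> None:
    for a in annotations:
        text = documents.get(a.doc_id)
        if text is None:
            raise ValueError(f"annotation references unknown document {a.doc_id!r}")
        if text[a.start : a.end] != a.text:
            raise ValueError(
                f"{a.doc_id}: annotation text {a.text!r} does not match the "
                f"document slice at [{a.start}, {a.end})"
            )


def _match_exact(a: list[StandoffAnnotation], b: list[StandoffAnnotation]) -> int:
    remaining = [(x.start, x.end) for x in b]
    tp = 0
    for x in a:
        key = (x.start, x.end)
        if key in remaining:
            remaining.remove(key)
            tp += 1
    return tp


def _match_overlap(a: list[StandoffAnnotation], b: list[StandoffAnnotation]) -> int:
    """Greedy one-to-one matching by span order, any positional intersection."""
    b_sorted = sorted(b, key=lambda x: (x.start, x.end))
    used = [False] * len(b_sorted)
    tp = 0
    for x in sorted(a, key=lambda x: (x.start, x.end)):
        for j, y in enumerate(b_sorted):
            if not used[j] and x.start < y.end and y.start < x.end:
                used[j] = True
                tp += 1
                break
    return tp


def compare(
    set_a: Sequence[StandoffAnnotation],
    set_b: Sequence[StandoffAnnotation],
    match_mode: str = "exact",
    documents: Optional[dict[str, str]] = None,
) -> tuple[ConfusionCounts, list[StandoffAnnotation]]:
    """Compare two annotation sets, treating *set_a* as the gold standard.

    Returns the confusion counts (tp = matched one-to-one, fp = B-only,
    fn = A-only) and the list of disagreeing annotations (the unmatched
    ones from both sides), ordered by document then span.
    """
    if match_mode not in ("exact", "overlap"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    if documents is not None:
        _validate_against_documents(list(set_a) + list(set_b), documents)

    by_doc_a: dict[str, list[StandoffAnnotation]] = {}
    by_doc_b: dict[str, list[StandoffAnnotation]] = {}
    for x in set_a:
        by_doc_a.setdefault(x.doc_id, []).append(x)
    for x in set_b:
        by_doc_b.setdefault(x.doc_id, []).append(x)

    matcher = _match_exact if match_mode == "exact" else _match_overlap
    tp = 0
    for doc_id in set(by_doc_a) | set(by_doc_b):
        tp += matcher(by_doc_a.get(doc_id, []), by_doc_b.get(doc_id, []))
    fn = len(set_a) - tp
    fp = len(set_b) - tp

    disagreements = _disagreements(by_doc_a, by_doc_b, match_mode)
    return ConfusionCounts(tp, fp, fn), disagreements


def _disagreements(by_doc_a, by_doc_b, match_mode) -> list[StandoffAnnotation]:
    out: list[StandoffAnnotation] = []
    for doc_id in set(by_doc_a) | set(by_doc_b):
        a = sorted(by_doc_a.get(doc_id, []), key=lambda x: (x.start, x.end))
        b = sorted(by_doc_b.get(doc_id, []), key=lambda x: (x.start, x.end))
        if match_mode == "exact":
            rem_b = [(y.start, y.end) for y in b]
            un_a = []
            for x in a:
                if (x.start, x.end) in rem_b:
                    rem_b.remove((x.start, x.end))
                else:
                    un_a.append(x)
            un_b = []
            rem_a = [(x.start, x.end) for x in a]
            for y in b:
                if (y.start, y.end) in rem_a:
                    rem_a.remove((y.start, y.end))
                else:
                    un_b.append(y)
        else:
            used = [False] * len(b)
            un_a = []
            for x in a:
                hit = None
                for j, y in enumerate(b):
                    if not used[j] and x.start < y.end and y.start < x.end:
                        hit = j
                        break
                if hit is None:
                    un_a.append(x)
                else:
                    used[hit] = True
            un_b = [y for j, y in enumerate(b) if not used[j]]
        out.extend(sorted(un_a + un_b, key=lambda x: (x.start, x.end)))
    return sorted(out, key=lambda x: (x.doc_id, x.start, x.end))


def agreement_metrics(counts: ConfusionCounts) -> Metrics:
    """Precision/recall/F1 from agreement counts (shared with evaluation)."""
    return prf(counts)
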