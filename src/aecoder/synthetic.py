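"""Synthetic SAE-narrative corpus generator.

Real SAE report narratives are confidential, so every part of the pipeline
is exercised on generated documents that emulate the statistical shape of
an annotated SAE corpus: short clinical notes (mean ~37 tokens), a handful
of coded adverse events per document (mean ~3.5), and roughly two thirds of
dictionary-surfaced candidates being genuine adverse events.  Documents are
assembled from templated clauses: positive frames place a concept in an
acute, now-occurring context (``admitted to hospital with {c}``), negative
frames place it in medical history, negation or hypothetical contexts
(``history of {c}``, ``no {c}``, ``monitor for {c}``).  The label of every
candidate is fully determined by its frame, which is precisely the
contextual signal the anchored classifier is meant to learn; no attempt is
made to mimic free clinical style beyond the frames.

The generator also plants *lookup misses*: adverse events expressed by a
paraphrase that is absent from the lexicon (``breathlessness`` for
dyspnea), which the dictionary stage can never surface and which the
evaluation therefore amalgamates into the false negatives.  A simulated
second annotator (random span drops and spurious additions) supports the
inter-annotator-agreement machinery, and a small set of frozen hard cases
reproduces known failure patterns: negation scope, polarity words such as
*decreased*, and one concept used in several contexts at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from ._tokens import tokenize_with_offsets
from .agreement import StandoffAnnotation
from .anchoring import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    CandidateInstance,
    GoldLabeling,
    label_candidates,
    make_candidates,
    write_candidates_jsonl,
)
from .lexicon import Lexicon, find_concept_mentions, load_lexicon
from .preprocess import AbbreviationTable, load_abbreviations, normalize

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "toy_lexicon",
    "default_abbreviations",
    "generate_corpus",
    "simulate_second_annotator",
    "annotator_pair_fixture",
    "hard_case_fixtures",
    "write_hard_cases",
    "PARAPHRASES",
]

_POSITIVE_FRAMES = [
    "admitted to hospital with {}",
    "patient experienced {}",
    "admitted with {}",
    "presented with {}",
    "developed {}",
    "complained of {}",
]
_REPEAT_FRAMES = [
    "still reporting {}",
    "ongoing {} overnight",
]
_HISTORY_FRAMES = [
    "history of {}",
    "known to have {}",
    "previous episode of {}",
    "long standing {}",
]
_NEGATION_FRAMES = [
    "no {}",
    "no evidence of {}",
    "denied {}",
    "scan showed no {}",
]
_HYPOTHETICAL_FRAMES = [
    "monitor for {}",
    "at risk of {}",
    "advised to report any {}",
]
_OPENER_CLAUSES = [
    "patient on trial medication reviewed today",
    "routine review of patient on study drug",
    "report received from the local site team",
    "narrative provided by the reviewing physician",
    "patient seen in clinic for scheduled visit",
]
_FILLER_CLAUSES = [
    "observations stable overnight",
    "bloods reviewed on admission",
    "plan discussed with the team",
    "fluids commenced on the ward",
    "seen by the on call doctor",
]

#: Surface paraphrases deliberately absent from the toy lexicon, used to
#: plant dictionary-lookup misses.  None of them contains a lexicon term
#: at token boundaries, so a planted miss surfaces no candidate at all.
PARAPHRASES = {
    "C0013404": "breathlessness",
    "C0042963": "emesis",
    "C0015672": "tiredness",
    "C0011991": "loose stools",
    "C0027497": "queasiness",
    "C0015967": "high temperature",
    "C0020649": "low blood pressure",
    "C0018681": "cephalalgia",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    n_documents: int = 200
    seed: int = 0
    mean_tokens: float = 37.0
    mean_labels_per_doc: float = 3.5
    positive_candidate_fraction: float = 0.662
    #: history / negation / hypothetical weights for negative contexts
    negative_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    lookup_miss_rate: float = 0.15
    annotator_miss_rate: float = 98 / 842
    annotator_spurious_rate: float = 50 / 842
    repeat_mention_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        for name in ("positive_candidate_fraction", "lookup_miss_rate",
                     "annotator_miss_rate", "annotator_spurious_rate",
                     "repeat_mention_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.negative_mix) < 0 or sum(self.negative_mix) <= 0:
            raise ValueError("negative_mix weights must be non-negative, not all 0")
        if self.mean_labels_per_doc < 1:
            raise ValueError("mean_labels_per_doc must be >= 1")

    @property
    def ae_probability(self) -> float:
        """Per-concept probability of being a gold adverse event.

        Chosen so that after removing planted lookup misses the surfaced
        candidates are positive with probability
        ``positive_candidate_fraction``.
        """
        f = self.positive_candidate_fraction
        m = self.lookup_miss_rate
        return f / (f + (1 - m) * (1 - f))


@dataclass
class SyntheticCorpus:
    """Generated documents with gold annotations and full bookkeeping."""

    texts: dict[str, str]
    gold_annotations: dict[str, list[StandoffAnnotation]]
    gold_labels: dict[str, GoldLabeling]
    #: per document: CUI -> positive/negative for lookup-surfaceable concepts
    true_candidate_labels: dict[str, dict[str, str]]
    #: per document: gold CUIs expressed only by an out-of-lexicon paraphrase
    planted_misses: dict[str, set[str]]
    config: GeneratorConfig

    @property
    def doc_ids(self) -> list[str]:
        return sorted(self.texts)

    def write(self, directory: str | Path) -> None:
        """Write texts (JSONL) and gold annotations (.ann) to *directory*."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with (d / "corpus.jsonl").open("w", encoding="utf-8") as fh:
            for doc_id in self.doc_ids:
                fh.write(json.dumps({"doc_id": doc_id, "text": self.texts[doc_id]},
                                    sort_keys=True) + "\n")
        ann_dir = d / "gold"
        ann_dir.mkdir(exist_ok=True)
        from .agreement import write_ann

        for doc_id in self.doc_ids:
            write_ann(self.gold_annotations[doc_id], ann_dir / f"{doc_id}.ann")


def toy_lexicon() -> Lexicon:
    """The bundled ~60-concept lexicon."""
    with resources.as_file(
        resources.files("aecoder").joinpath("data/lexicon.tsv")
    ) as p:
        return load_lexicon(p)


def default_abbreviations() -> AbbreviationTable:
    with resources.as_file(
        resources.files("aecoder").joinpath("data/abbreviations.tsv")
    ) as p:
        return load_abbreviations(p)


def _surface(lexicon: Lexicon, cui: str, rng: np.random.Generator) -> str:
    """A lexicon surface form for *cui* (preferred name most of the time)."""
    terms = [e.term for e in lexicon.entries if e.cui == cui]
    if len(terms) > 1 and rng.random() < 0.3:
        return terms[int(rng.integers(len(terms)))]
    return lexicon.preferred_name(cui)


def generate_corpus(
    cfg: GeneratorConfig, lexicon: Optional[Lexicon] = None
) -> SyntheticCorpus:
    """Generate a fully seeded corpus matching the configured shape."""
    lexicon = lexicon or toy_lexicon()
    rng = np.random.default_rng(cfg.seed)
    all_cuis = sorted(lexicon.cuis)
    paraphrase_cuis = sorted(set(PARAPHRASES) & set(all_cuis))
    if cfg.lookup_miss_rate > 0 and not paraphrase_cuis:
        raise ValueError("lookup_miss_rate > 0 requires paraphrasable concepts")

    q = cfg.ae_probability
    lam = max(cfg.mean_labels_per_doc / q - 1.0, 0.0)

    texts: dict[str, str] = {}
    gold_ann: dict[str, list[StandoffAnnotation]] = {}
    gold_lab: dict[str, GoldLabeling] = {}
    true_labels: dict[str, dict[str, str]] = {}
    misses: dict[str, set[str]] = {}

    for d in range(cfg.n_documents):
        doc_id = f"doc-{d:04d}"
        n_concepts = 1 + int(rng.poisson(lam))
        if n_concepts > len(all_cuis):
            raise ValueError(
                f"document requires {n_concepts} distinct concepts but the "
                f"lexicon has only {len(all_cuis)} CUIs"
            )

        # decide roles first, then draw compatible CUIs without replacement
        roles = []  # (is_ae, is_miss)
        for _ in range(n_concepts):
            is_ae = rng.random() < q
            is_miss = is_ae and rng.random() < cfg.lookup_miss_rate
            roles.append((is_ae, is_miss))
        available = list(all_cuis)
        chosen: list[tuple[str, bool, bool]] = []
        for is_ae, is_miss in roles:
            pool = (
                [c for c in paraphrase_cuis if c in available]
                if is_miss
                else available
            )
            if not pool:
                is_miss = False
                pool = available
            cui = pool[int(rng.integers(len(pool)))]
            available.remove(cui)
            chosen.append((cui, is_ae, is_miss))

        # each clause: (frame, payload); payload = (cui-or-None, term) where a
        # non-None cui marks a gold adverse-event mention to annotate
        clauses: list[tuple[str, Optional[tuple[Optional[str], str]]]] = []
        neg_w = np.array(cfg.negative_mix, dtype=float)
        neg_w = neg_w / neg_w.sum()
        for cui, is_ae, is_miss in chosen:
            if is_ae:
                term = PARAPHRASES[cui] if is_miss else _surface(lexicon, cui, rng)
                frame = _POSITIVE_FRAMES[int(rng.integers(len(_POSITIVE_FRAMES)))]
                clauses.append((frame, (cui, term)))
                if not is_miss and rng.random() < cfg.repeat_mention_rate:
                    rep = _REPEAT_FRAMES[int(rng.integers(len(_REPEAT_FRAMES)))]
                    clauses.append((rep, (cui, term)))
            else:
                term = _surface(lexicon, cui, rng)
                family = [_HISTORY_FRAMES, _NEGATION_FRAMES, _HYPOTHETICAL_FRAMES][
                    int(rng.choice(3, p=neg_w))
                ]
                frame = family[int(rng.integers(len(family)))]
                clauses.append((frame, (None, term)))

        rng.shuffle(clauses)
        if rng.random() < 0.8:
            filler = _FILLER_CLAUSES[int(rng.integers(len(_FILLER_CLAUSES)))]
            clauses.insert(int(rng.integers(len(clauses) + 1)), (filler, None))
        opener = _OPENER_CLAUSES[int(rng.integers(len(_OPENER_CLAUSES)))]
        clauses.insert(0, (opener, None))

        parts: list[str] = []
        ann: list[StandoffAnnotation] = []
        pos = 0
        for frame, payload in clauses:
            if payload is None:
                clause = frame
            else:
                cui, term = payload
                offset = frame.index("{}")
                clause = frame.format(term)
                if cui is not None:  # gold adverse-event mention
                    start = pos + offset
                    ann.append(
                        StandoffAnnotation(doc_id, start, start + len(term),
                                           term, cui)
                    )
            parts.append(clause + " .")
            pos += len(clause) + 3  # clause, space, period, space
        text = " ".join(parts)
        texts[doc_id] = text
        gold_ann[doc_id] = ann

        ae_cuis = {cui for cui, is_ae, _ in chosen if is_ae}
        gold_lab[doc_id] = GoldLabeling(doc_id, ae_cuis)
        misses[doc_id] = {cui for cui, is_ae, is_miss in chosen if is_miss}
        true_labels[doc_id] = {
            cui: (LABEL_POSITIVE if is_ae else LABEL_NEGATIVE)
            for cui, is_ae, is_miss in chosen
            if not is_miss
        }

    return SyntheticCorpus(texts, gold_ann, gold_lab, true_labels, misses, cfg)


def _free_word_tokens(
    text: str, taken: list[StandoffAnnotation]
) -> list[tuple[int, int, str]]:
    """Word tokens of *text* not covered by any annotation in *taken*."""
    out = []
    for tok, s, e in tokenize_with_offsets(text):
        if len(tok) < 3 or not tok.isalpha():
            continue
        if any(a.start < e and s < a.end for a in taken):
            continue
        out.append((s, e, tok))
    return out


def simulate_second_annotator(
    corpus: SyntheticCorpus,
    miss_rate: Optional[float] = None,
    spurious_rate: Optional[float] = None,
    seed: Optional[int] = None,
) -> list[StandoffAnnotation]:
    """An imperfect independent re-annotation of the gold spans.

    Each gold span is dropped with probability *miss_rate*; for each gold
    span, with probability *spurious_rate* an extra span is placed on a
    free word of the same document.  Defaults come from the corpus config;
    fully seeded.
    """
    cfg = corpus.config
    miss = cfg.annotator_miss_rate if miss_rate is None else miss_rate
    spur = cfg.annotator_spurious_rate if spurious_rate is None else spurious_rate
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    out: list[StandoffAnnotation] = []
    for doc_id in corpus.doc_ids:
        gold = corpus.gold_annotations[doc_id]
        for a in gold:
            if rng.random() >= miss:
                out.append(a)
            if rng.random() < spur:
                doc_out = [x for x in out if x.doc_id == doc_id]
                free = _free_word_tokens(corpus.texts[doc_id], gold + doc_out)
                if free:
                    s, e, tok = free[int(rng.integers(len(free)))]
                    out.append(StandoffAnnotation(doc_id, s, e, tok))
    return out


def annotator_pair_fixture(
    n_matches: int = 744,
    n_a_only: int = 98,
    n_b_only: int = 50,
    seed: int = 0,
) -> tuple[list[StandoffAnnotation], list[StandoffAnnotation], dict[str, str]]:
    """Two annotation sets with exact agreement counts, plus their texts.

    Deterministically partitions the gold spans of a generated corpus into
    shared and A-only spans and plants B-only spans on free words, so that
    ``compare(A, B)`` yields exactly (tp, fp, fn) = (n_matches, n_b_only,
    n_a_only) in both exact and overlap matching modes.
    """
    need = n_matches + n_a_only
    cfg = GeneratorConfig(n_documents=max(60, (need // 3) + 40), seed=seed)
    corpus = generate_corpus(cfg)
    flat: list[StandoffAnnotation] = []
    for doc_id in corpus.doc_ids:
        flat.extend(corpus.gold_annotations[doc_id])
    if len(flat) < need:
        raise ValueError(
            f"fixture needs {need} gold spans but the corpus produced {len(flat)}"
        )
    set_a = flat[:need]
    set_b = list(flat[:n_matches])
    rng = np.random.default_rng(seed + 17)
    placed = 0
    for doc_id in corpus.doc_ids:
        if placed >= n_b_only:
            break
        free = _free_word_tokens(
            corpus.texts[doc_id], corpus.gold_annotations[doc_id]
        )
        if free:
            s, e, tok = free[int(rng.integers(len(free)))]
            set_b.append(StandoffAnnotation(doc_id, s, e, tok))
            placed += 1
    if placed < n_b_only:
        raise ValueError("could not place all spurious annotations")
    return set_a, set_b, dict(corpus.texts)


# -- frozen hard cases ----------------------------------------------------

#: (doc_id, text, gold CUIs) — known systematic failure patterns: negation
#: scope, polarity words (*decreased*), one concept in multiple contexts.
_HARD_CASES: list[tuple[str, str, frozenset]] = [
    (
        "hc-negation-1",
        "Chest X-ray showed no new lesion, no pleural effusion disorder "
        "or pneumothorax and history of smoking.",
        frozenset(),
    ),
    (
        "hc-negation-2",
        "Admitted with right scaptula/back pain, no chest pain or dyspnea.",
        frozenset({"C0004604"}),
    ),
    (
        "hc-polarity-pos",
        "Patient reported decreased mobility following treatment.",
        frozenset({"C0587597"}),
    ),
    (
        "hc-polarity-neg",
        "Patient reported decreased pain following treatment.",
        frozenset(),
    ),
    (
        "hc-multi-context",
        "Admitted to hospital with lower respiratory tract infection. "
        "Not commenced chemotherapy related infection.",
        frozenset({"C0035243", "C3714514"}),
    ),
]


def hard_case_fixtures(lexicon: Optional[Lexicon] = None) -> list[CandidateInstance]:
    """Labeled challenge candidates built through the real pipeline.

    These reproduce documented failure modes and are reported on, not
    asserted: a context classifier without explicit negation handling is
    expected to get several of them wrong.
    """
    lexicon = lexicon or toy_lexicon()
    out: list[CandidateInstance] = []
    for doc_id, text, gold_cuis in _HARD_CASES:
        doc = normalize(text, doc_id=doc_id)
        mentions = find_concept_mentions(doc.normalized_text, lexicon)
        cands = make_candidates(doc, mentions, lexicon)
        labeled, _missed = label_candidates(cands, GoldLabeling(doc_id, gold_cuis))
        out.extend(labeled)
    return out


def write_hard_cases(path: str | Path, lexicon: Optional[Lexicon] = None) -> None:
    """Serialize the hard cases (byte-stable across runs)."""
    write_candidates_jsonl(hard_case_fixtures(lexicon), path)
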