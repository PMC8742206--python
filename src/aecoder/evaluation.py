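"""Cross-validated evaluation with false-negative amalgamation.

Coding performance is scored at the document level on CUIs: true positives
are candidates the classifier accepts that are gold adverse events, false
positives are accepted non-events, false negatives are rejected gold
events.  Gold adverse events that the dictionary lookup never surfaced
cannot reach the classifier; the *amalgamation* rule adds them to the false
negatives of the end-to-end system, which leaves precision untouched and
can only lower recall.

Cross-validation is grouped by document — all candidates of a document
share its fold — and repeated: metrics are averaged over the k folds of a
run, then mean and standard deviation are taken over independent runs.
ROC and precision-recall curves (with trapezoidal AUC and no-skill
references) and the prediction-probability histogram are computed from the
pooled per-candidate probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve as _sk_pr
from sklearn.metrics import roc_curve as _sk_roc

from .anchoring import LABEL_POSITIVE, CandidateInstance

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "prf",
    "amalgamate",
    "grouped_folds",
    "roc_curve",
    "pr_curve",
    "auc_score",
    "probability_histogram",
    "confusion_from_predictions",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN counts; true negatives are undefined by construction."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """Precision, recall and F1 (division-by-zero cases defined as 0)."""

    precision: float
    recall: float
    f1: float


def prf(counts: ConfusionCounts) -> Metrics:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p, r, f1)


def amalgamate(counts: ConfusionCounts, missed: int) -> ConfusionCounts:
    """Fold dictionary-lookup misses into the false negatives."""
    if missed < 0:
        raise ValueError("missed must be non-negative")
    return ConfusionCounts(counts.tp, counts.fp, counts.fn + missed)


def grouped_folds(doc_ids: Sequence[str], k: int = 5,
                  seed: int = 0) -> dict[str, int]:
    """Shuffle documents and split them into *k* folds of near-equal size.

    Returns a document-id -> fold-index map; every candidate of a document
    inherits its fold, so no document straddles folds.
    """
    ids = list(doc_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("doc_ids must be unique")
    if k < 2 or k > len(ids):
        raise ValueError(f"k={k} incompatible with {len(ids)} documents")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment: dict[str, int] = {}
    for pos, idx in enumerate(order):
        assignment[ids[idx]] = pos % k
    return assignment


def confusion_from_predictions(
    predicted_positive: Sequence[bool],
    gold_positive: Sequence[bool],
) -> ConfusionCounts:
    tp = fp = fn = 0
    for pred, gold in zip(predicted_positive, gold_positive, strict=True):
        if pred and gold:
            tp += 1
        elif pred and not gold:
            fp += 1
        elif gold:
            fn += 1
    return ConfusionCounts(tp, fp, fn)


# -- curves ---------------------------------------------------------------

def roc_curve(scores: Sequence[float], labels: Sequence[int]):
    """(fpr, tpr, auc) of the step ROC curve."""
    fpr, tpr, _ = _sk_roc(np.asarray(labels), np.asarray(scores))
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def pr_curve(scores: Sequence[float], labels: Sequence[int]):
    """(recall, precision, auc) of the PR curve, anchored at the recall
    extremes."""
    prec, rec, _ = _sk_pr(np.asarray(labels), np.asarray(scores))
    # sklearn returns decreasing recall; integrate on the increasing axis
    return rec[::-1], prec[::-1], float(_sk_auc(rec[::-1], prec[::-1]))


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    return roc_curve(scores, labels)[2]


def probability_histogram(probabilities: Sequence[float],
                          bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of prediction probabilities over [0, 1]."""
    counts, edges = np.histogram(np.asarray(probabilities), bins=bins,
                                 range=(0.0, 1.0))
    return counts, edges


# -- cross-validation -----------------------------------------------------

@dataclass
class EvalReport:
    """Results of one repeated grouped-CV experiment."""

    runs: int
    k: int
    #: per run, per fold metrics
    fold_metrics: list[list[Metrics]]
    fold_metrics_amalgamated: list[list[Metrics]]
    #: two-stage aggregation: fold mean per run, then mean/SD over runs
    mean: Metrics = field(init=False)
    sd: Metrics = field(init=False)
    mean_amalgamated: Metrics = field(init=False)
    sd_amalgamated: Metrics = field(init=False)
    fold_auc_roc: list[list[float]] = field(default_factory=list)
    fold_auc_pr: list[list[float]] = field(default_factory=list)
    pooled_probs: np.ndarray = field(default_factory=lambda: np.empty(0))
    pooled_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    positive_prevalence: float = 0.0

    def __post_init__(self) -> None:
        self.mean, self.sd = _two_stage(self.fold_metrics)
        self.mean_amalgamated, self.sd_amalgamated = _two_stage(
            self.fold_metrics_amalgamated)

    @property
    def auc_roc_mean(self) -> float:
        return float(np.mean([np.mean(r) for r in self.fold_auc_roc]))

    @property
    def auc_roc_sd(self) -> float:
        return float(np.std([np.mean(r) for r in self.fold_auc_roc]))

    @property
    def auc_pr_mean(self) -> float:
        return float(np.mean([np.mean(r) for r in self.fold_auc_pr]))

    def histogram(self, bins: int = 20):
        return probability_histogram(self.pooled_probs, bins)

    def no_skill(self) -> dict:
        """No-skill references: ROC diagonal; PR line at positive prevalence."""
        return {"roc_auc": 0.5, "pr_auc": self.positive_prevalence}

    def to_dict(self) -> dict:
        def m(x: Metrics) -> dict:
            return {"precision": x.precision, "recall": x.recall, "f1": x.f1}

        return {
            "runs": self.runs,
            "k": self.k,
            "classifier_only": {"mean": m(self.mean), "sd": m(self.sd)},
            "end_to_end": {"mean": m(self.mean_amalgamated),
                           "sd": m(self.sd_amalgamated)},
            "auc_roc": {"mean": self.auc_roc_mean, "sd": self.auc_roc_sd},
            "auc_pr": {"mean": self.auc_pr_mean},
            "positive_prevalence": self.positive_prevalence,
            "no_skill": self.no_skill(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_curves(self, path: str | Path) -> None:
        """Write pooled ROC and PR curve points as CSV."""
        fpr, tpr, _ = roc_curve(self.pooled_probs, self.pooled_labels)
        rec, prec, _ = pr_curve(self.pooled_probs, self.pooled_labels)
        lines = ["curve,x,y"]
        lines += [f"roc,{x:.6f},{y:.6f}" for x, y in zip(fpr, tpr)]
        lines += [f"pr,{x:.6f},{y:.6f}" for x, y in zip(rec, prec)]
        Path(path).write_text("\n".join(lines) + "\n")

    def plot(self, directory: str | Path) -> None:
        """Optional ROC/PR/histogram figures (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        fpr, tpr, auc_v = roc_curve(self.pooled_probs, self.pooled_labels)
        fig, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"model (AUC {auc_v:.3f})")
        ax.plot([0, 1], [0, 1], "k--", label="no skill")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        fig.savefig(d / "roc.png", dpi=120)
        plt.close(fig)

        rec, prec, auc_p = pr_curve(self.pooled_probs, self.pooled_labels)
        fig, ax = plt.subplots()
        ax.plot(rec, prec, label=f"model (AUC {auc_p:.3f})")
        ax.axhline(self.positive_prevalence, color="k", ls="--",
                   label="no skill")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.legend()
        fig.savefig(d / "pr.png", dpi=120)
        plt.close(fig)

        counts, edges = self.histogram()
        fig, ax = plt.subplots()
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("count")
        fig.savefig(d / "probability_histogram.png", dpi=120)
        plt.close(fig)


def _two_stage(per_run: list[list[Metrics]]) -> tuple[Metrics, Metrics]:
    """Mean over folds within a run, then mean and SD over run means."""
    if not per_run:
        z = Metrics(0.0, 0.0, 0.0)
        return z, z
    run_means = np.array(
        [[np.mean([f.precision for f in run]),
          np.mean([f.recall for f in run]),
          np.mean([f.f1 for f in run])] for run in per_run]
    )
    mean = run_means.mean(axis=0)
    sd = run_means.std(axis=0)
    return Metrics(*map(float, mean)), Metrics(*map(float, sd))


def cross_validate(
    candidates_by_doc: dict[str, list[CandidateInstance]],
    missed_by_doc: dict[str, set],
    make_estimator: Callable[[int], object],
    runs: int = 10,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Repeated document-grouped k-fold CV of the anchored classifier.

    ``make_estimator(seed)`` must return an unfitted sklearn-style
    classifier over candidate instances (cloned internally, so a prototype
    closure is fine).  Classifier-only metrics score the candidates the
    lookup surfaced; the amalgamated variant adds lookup-missed gold CUIs
    of the evaluation documents to the false negatives.
    """
    doc_ids = sorted(candidates_by_doc)
    fold_metrics: list[list[Metrics]] = []
    fold_metrics_am: list[list[Metrics]] = []
    fold_auc_roc: list[list[float]] = []
    fold_auc_pr: list[list[float]] = []
    all_probs: list[float] = []
    all_labels: list[int] = []

    for run in range(runs):
        run_seed = seed + 1000 * run
        assignment = grouped_folds(doc_ids, k=k, seed=run_seed)
        fm, fma, far, fap = [], [], [], []
        for fold in range(k):
            test_docs = [d for d in doc_ids if assignment[d] == fold]
            train_docs = [d for d in doc_ids if assignment[d] != fold]
            train_c = [c for d in train_docs for c in candidates_by_doc[d]]
            test_c = [c for d in test_docs for c in candidates_by_doc[d]]
            est = clone(make_estimator(run_seed + fold))
            est.fit(train_c)
            probs = est.predict_proba(test_c)[:, 1]
            gold = np.array([c.label == LABEL_POSITIVE for c in test_c])
            pred = probs >= threshold
            counts = confusion_from_predictions(pred, gold)
            missed = sum(len(missed_by_doc.get(d, ())) for d in test_docs)
            fm.append(prf(counts))
            fma.append(prf(amalgamate(counts, missed)))
            if gold.any() and (~gold).any():
                far.append(auc_score(probs, gold.astype(int)))
                fap.append(pr_curve(probs, gold.astype(int))[2])
            all_probs.extend(probs.tolist())
            all_labels.extend(gold.astype(int).tolist())
        fold_metrics.append(fm)
        fold_metrics_am.append(fma)
        fold_auc_roc.append(far)
        fold_auc_pr.append(fap)

    labels_arr = np.array(all_labels)
    return EvalReport(
        runs=runs,
        k=k,
        fold_metrics=fold_metrics,
        fold_metrics_amalgamated=fold_metrics_am,
        fold_auc_roc=fold_auc_roc,
        fold_auc_pr=fold_auc_pr,
        pooled_probs=np.array(all_probs),
        pooled_labels=labels_arr,
        positive_prevalence=float(labels_arr.mean()) if labels_arr.size else 0.0,
    )
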