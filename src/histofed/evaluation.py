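"""Retrieval evaluation: ACC@K, precision, F1 and top-K confusion matrices.

ACC@K is the any-match statistic used throughout retrieval benchmarking:

    ACC@K = (1/N) * sum_i eps_i,   eps_i = 1 iff any of the top-K hit labels
                                            equals the query label alpha_i,

computed here with K = 5 by default.  Precision and F1 additionally need one
predicted label per query; the default rule is a majority vote over the
top-K hit labels with ties resolved by the nearest hit (a rank-1 rule and a
per-hit micro-averaged variant are available).  The positive class is
malignant/cancerous (label 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .retrieval import RetrievalResult
from .types import MALIGNANT, PatchImage

LABEL_RULES = ("majority", "rank1", "per_hit")


@dataclass
class PerQuery:
    query_id: str
    true_label: int
    predicted_label: int | None
    any_match: int


@dataclass
class EvalReport:
    n_queries: int
    k: int
    acc_at_k: float
    precision: float
    recall: float
    f1: float
    confusion_matrix: np.ndarray  # rows: true label 0/1, cols: predicted 0/1
    per_query: list[PerQuery] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "k": self.k,
            "acc_at_k": self.acc_at_k,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion_matrix": self.confusion_matrix.tolist(),
        }


def _labels_of(queries: Sequence) -> list[int]:
    out = []
    for q in queries:
        label = q.label if isinstance(q, PatchImage) or hasattr(q, "label") else q
        if label is None:
            raise ValueError("every query needs a label for evaluation")
        out.append(int(label))
    return out


def acc_at_k(queries: Sequence, results: Sequence[RetrievalResult], k: int = 5) -> float:
    """Fraction of queries with at least one top-K hit sharing the query label."""
    labels = _labels_of(queries)
    if not labels:
        raise ValueError("empty query set")
    if len(labels) != len(results):
        raise ValueError(f"{len(labels)} queries but {len(results)} results")
    eps = [
        1 if any(h.label == a for h in r.hits[:k]) else 0
        for a, r in zip(labels, results)
    ]
    return float(np.mean(eps))


def predict_label_topk(result: RetrievalResult, k: int = 5, rule: str = "majority") -> int:
    """Single predicted label for one query from its ranked hits."""
    hits = result.hits[:k]
    if not hits:
        raise ValueError(f"query {result.query_id!r} has no hits")
    if rule == "rank1":
        return int(hits[0].label)
    if rule != "majority":
        raise ValueError(f"unknown label rule {rule!r}")
    counts: dict[int, int] = {}
    for h in hits:
        counts[int(h.label)] = counts.get(int(h.label), 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    return int(hits[0].label)  # tie: defer to the nearest hit


def evaluate(
    queries: Sequence,
    results: Sequence[RetrievalResult],
    k: int = 5,
    rule: str = "majority",
    positive_label: int = MALIGNANT,
) -> EvalReport:
    """Full report over a query set: ACC@K plus label-based metrics.

    With ``rule="per_hit"`` every retrieved hit counts as one prediction
    (micro-averaging over N*K pairs); the confusion matrix then counts hits,
    not queries, and per-query predicted labels are omitted.
    """
    labels = _labels_of(queries)
    if not labels:
        raise ValueError("empty query set")
    if len(labels) != len(results):
        raise ValueError(f"{len(labels)} queries but {len(results)} results")
    if rule not in LABEL_RULES:
        raise ValueError(f"unknown label rule {rule!r}; choose from {LABEL_RULES}")

    acck = acc_at_k(labels, results, k)

    cm = np.zeros((2, 2), dtype=int)
    per_query: list[PerQuery] = []
    if rule == "per_hit":
        for a, r in zip(labels, results):
            match = 1 if any(h.label == a for h in r.hits[:k]) else 0
            per_query.append(PerQuery(r.query_id, a, None, match))
            for h in r.hits[:k]:
                cm[a, int(h.label)] += 1
    else:
        for a, r in zip(labels, results):
            pred = predict_label_topk(r, k, rule)
            match = 1 if any(h.label == a for h in r.hits[:k]) else 0
            per_query.append(PerQuery(r.query_id, a, pred, match))
            cm[a, pred] += 1

    pos = positive_label
    neg = 1 - pos
    tp = int(cm[pos, pos])
    fp = int(cm[neg, pos])
    fn = int(cm[pos, neg])
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    return EvalReport(
        n_queries=len(labels),
        k=k,
        acc_at_k=acck,
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        confusion_matrix=cm,
        per_query=per_query,
    )
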