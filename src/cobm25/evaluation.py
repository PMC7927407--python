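"""Retrieval metrics: P@k, nDCG, R-precision, precision/recall/F1, and the
co-word coverage rate, per topic and averaged.

Relevance is graded (0 = not relevant). A document counts as relevant for
the binary metrics when its grade is >= 1. nDCG uses

    DCG = sum_{i=1..Z} gain(grade_i) / log(i + 1)

normalized by the DCG of the ideal ordering of *all judged* documents for
the topic, truncated at the same depth Z; the log base cancels in the
ratio. Gains are linear (gain = grade) by default; exponential
``2^grade - 1`` gains are available by flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .corpus_io import Qrels, RunEntry

logger = logging.getLogger(__name__)


def _ranked_doc_ids(entries: Sequence[RunEntry]) -> list[str]:
    return [e.doc_id for e in sorted(entries, key=lambda e: e.rank)]


def _gain(grade: int, exponential: bool) -> float:
    return float(2 ** grade - 1) if exponential else float(grade)


def precision_at_k(ranked_docs: Sequence[str], qrels: Qrels, topic_id: str,
                   k: int = 10) -> float:
    """Fraction of relevant documents among the first k; the denominator
    stays k even when fewer than k documents were retrieved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(1 for d in ranked_docs[:k] if qrels.grade(topic_id, d) >= 1)
    return hits / k


def ndcg(ranked_docs: Sequence[str], qrels: Qrels, topic_id: str,
         z: int = 1000, exponential_gain: bool = False) -> float:
    """Normalized discounted cumulative gain at depth z.

    The ideal list orders all judged documents for the topic by
    non-increasing grade; topics with no relevant document score 0.
    """
    if z < 1:
        raise ValueError("z must be >= 1")
    judged = qrels.judged(topic_id)
    ideal_gains = sorted(
        (_gain(g, exponential_gain) for g in judged.values()), reverse=True
    )[:z]
    dcg_i = sum(g / math.log(i + 2) for i, g in enumerate(ideal_gains) if g > 0)
    if dcg_i == 0.0:
        return 0.0
    dcg = sum(
        _gain(qrels.grade(topic_id, d), exponential_gain) / math.log(i + 2)
        for i, d in enumerate(ranked_docs[:z])
    )
    return dcg / dcg_i


def r_precision(ranked_docs: Sequence[str], qrels: Qrels, topic_id: str) -> float:
    """Precision at rank R where R is the topic's relevant-document count."""
    R = len(qrels.relevant(topic_id))
    if R == 0:
        logger.warning("topic %s has no relevant documents; R-precision set to 0",
                       topic_id)
        return 0.0
    hits = sum(1 for d in ranked_docs[:R] if qrels.grade(topic_id, d) >= 1)
    return hits / R


def recall_f1(ranked_docs: Sequence[str], qrels: Qrels, topic_id: str) -> tuple[float, float]:
    """(recall, F1) at the full run cutoff: RR/(RR+NR) and 2PR/(P+R)."""
    relevant = qrels.relevant(topic_id)
    retrieved = list(ranked_docs)
    rr = sum(1 for d in retrieved if d in relevant)
    precision = rr / len(retrieved) if retrieved else 0.0
    recall = rr / len(relevant) if relevant else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return recall, f1


def _group_runs(runs: Sequence[RunEntry]) -> dict[str, list[str]]:
    by_topic: dict[str, list[RunEntry]] = {}
    for e in runs:
        by_topic.setdefault(e.topic_id, []).append(e)
    return {t: _ranked_doc_ids(es) for t, es in by_topic.items()}


def avg_p10(runs: Sequence[RunEntry], qrels: Qrels, k: int = 10) -> float:
    """Mean P@10 over every topic in the qrels; unretrieved topics score 0."""
    topics = qrels.topics()
    if not topics:
        raise ValueError("qrels contain no topics")
    ranked = _group_runs(runs)
    return sum(
        precision_at_k(ranked.get(t, []), qrels, t, k) for t in topics
    ) / len(topics)


def avg_ndcg(runs: Sequence[RunEntry], qrels: Qrels, z: int = 1000,
             exponential_gain: bool = False) -> float:
    topics = qrels.topics()
    if not topics:
        raise ValueError("qrels contain no topics")
    ranked = _group_runs(runs)
    return sum(
        ndcg(ranked.get(t, []), qrels, t, z, exponential_gain) for t in topics
    ) / len(topics)


def coverage(qrels: Qrels, coword_docs: Mapping[str, set[str]]) -> float:
    """Average co-word coverage: per topic, the fraction of relevant
    documents that are co-word documents, averaged over topics.

    ``coword_docs`` maps topic_id -> set of doc_ids in which the topic's
    disease and gene co-occur. Topics with no relevant documents are
    excluded from the mean with a warning.
    """
    rates = []
    for t in qrels.topics():
        relevant = qrels.relevant(t)
        if not relevant:
            logger.warning("topic %s has no relevant documents; excluded from coverage", t)
            continue
        cw = coword_docs.get(t, set())
        rates.append(len(relevant & cw) / len(relevant))
    if not rates:
        raise ValueError("no topic has relevant documents")
    return sum(rates) / len(rates)


@dataclass
class EvalSummary:
    """Per-topic metric table plus the averages the objective function uses."""

    per_topic: pd.DataFrame
    avg_p10: float
    avg_ndcg: float
    avg_coverage: float | None = None
    extra: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lines = [self.per_topic.to_string(float_format=lambda v: f"{v:.4f}")]
        lines.append(f"Avg P@10  = {self.avg_p10:.4f}")
        lines.append(f"Avg nDCG  = {self.avg_ndcg:.4f}")
        if self.avg_coverage is not None:
            lines.append(f"Avg cov   = {self.avg_coverage:.4f}")
        return "\n".join(lines)


def evaluate_run(runs: Sequence[RunEntry], qrels: Qrels, depth: int = 1000,
                 exponential_gain: bool = False,
                 coword_docs: Mapping[str, set[str]] | None = None) -> EvalSummary:
    """Full per-topic evaluation of a run against qrels."""
    topics = qrels.topics()
    if not topics:
        raise ValueError("qrels contain no topics")
    ranked = _group_runs(runs)
    rows = []
    for t in topics:
        docs = ranked.get(t, [])[:depth]
        relevant = qrels.relevant(t)
        rr = sum(1 for d in docs if d in relevant)
        rn = len(docs) - rr
        nr = len(relevant) - rr
        recall, f1 = recall_f1(docs, qrels, t)
        rows.append({
            "topic": t,
            "p_at_10": precision_at_k(docs, qrels, t, 10),
            "ndcg": ndcg(docs, qrels, t, depth, exponential_gain),
            "r_prec": r_precision(docs, qrels, t),
            "precision": rr / len(docs) if docs else 0.0,
            "recall": recall,
            "f1": f1,
            "RR": rr, "RN": rn, "NR": nr,
        })
    table = pd.DataFrame(rows).set_index("topic")
    avg_cov = coverage(qrels, coword_docs) if coword_docs is not None else None
    return EvalSummary(
        per_topic=table,
        avg_p10=float(table["p_at_10"].mean()),
        avg_ndcg=float(table["ndcg"].mean()),
        avg_coverage=avg_cov,
    )
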