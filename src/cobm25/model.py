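"""Model / Results front end over the retrieval machinery.

:class:`CoWordBM25` binds a corpus index, expanded topics and (optionally)
relevance judgments into a single object; :meth:`CoWordBM25.fit` tunes the
five free parameters by Cuckoo Search and returns a
:class:`CoWordBM25Results` carrying the fitted vector, the optimization
trace and evaluation diagnostics, with a ``summary()`` in the spirit of
statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import (CorpusIndex, Document, Qrels, RunEntry, Topic,
                        build_index, parse_medline_xml, read_qrels, read_topics)
from .cuckoo import CSConfig, OptimizeResult, RetrievalObjective, optimize
from .evaluation import EvalSummary, evaluate_run
from .expansion import ExpandedQuery, ExpansionLexicon, build_expanded_query
from .scoring import CowordMode, ModelParams, QueryScorer
from .synthetic import SynthConfig, generate_collection

_PARAM_NAMES = ("k1", "k3", "b1", "b2", "alpha")


class CoWordBM25:
    """Composite abstract + expanded-word + co-word retrieval model.

    Parameters
    ----------
    index : CorpusIndex
        The indexed document collection.
    queries : sequence of ExpandedQuery
        The expanded topics to rank.
    qrels : Qrels, optional
        Graded judgments; required for ``evaluate`` and ``fit``.
    mode : {"cross", "within"}
        Co-word detection mode (default "cross": disease and gene may sit
        in different fields of the same document).
    """

    def __init__(self, index: CorpusIndex, queries: Sequence[ExpandedQuery],
                 qrels: Qrels | None = None, mode: CowordMode = "cross",
                 depth: int = 1000):
        if not queries:
            raise ValueError("no topics supplied")
        self.index = index
        self.queries = list(queries)
        self.qrels = qrels
        self.mode: CowordMode = mode
        self.depth = depth
        self._scorers: dict[str, QueryScorer] | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_collection(cls, documents: Sequence[Document], topics: Sequence[Topic],
                        qrels: Qrels | None = None,
                        lexicon: ExpansionLexicon | None = None,
                        mode: CowordMode = "cross", depth: int = 1000,
                        include_other: bool = True) -> "CoWordBM25":
        index = build_index(documents)
        queries = [build_expanded_query(t, lexicon, include_other) for t in topics]
        return cls(index, queries, qrels, mode, depth)

    @classmethod
    def from_files(cls, corpus_xml, topics_path, qrels_path=None,
                   lexicon_path=None, **kw) -> "CoWordBM25":
        documents = parse_medline_xml(corpus_xml)
        topics = read_topics(topics_path)
        qrels = read_qrels(qrels_path) if qrels_path else None
        lexicon = ExpansionLexicon.from_tsv(lexicon_path) if lexicon_path else None
        return cls.from_collection(documents, topics, qrels, lexicon, **kw)

    @classmethod
    def simulate(cls, config: SynthConfig | None = None, seed: int = 0,
                 mode: CowordMode = "cross", depth: int = 1000) -> "CoWordBM25":
        """Build the model on a generated synthetic collection."""
        coll = generate_collection(config or SynthConfig(), seed)
        model = cls.from_collection(coll["documents"], coll["topics"],
                                    coll["qrels"], mode=mode, depth=depth)
        model.truth = coll
        return model

    # ------------------------------------------------------------------
    def scorers(self) -> dict[str, QueryScorer]:
        if self._scorers is None:
            self._scorers = {
                q.topic_id: QueryScorer(q, self.index, mode=self.mode)
                for q in self.queries
            }
        return self._scorers

    def _resolve(self, params) -> ModelParams:
        if isinstance(params, ModelParams):
            return params
        if isinstance(params, str):
            return ModelParams.preset(params)
        return ModelParams.from_vector(np.asarray(params, dtype=float))

    def rank(self, params="normal", top_k: int | None = None,
             tag: str = "cobm25") -> list[RunEntry]:
        """Rank every topic; returns the concatenated run."""
        p = self._resolve(params)
        k = top_k or self.depth
        runs: list[RunEntry] = []
        for q in self.queries:
            runs.extend(self.scorers()[q.topic_id].rank(p, k, tag))
        return runs

    def coword_documents(self) -> dict[str, set[str]]:
        """Ground-truth co-word document sets per topic (current mode)."""
        out: dict[str, set[str]] = {}
        for q in self.queries:
            flags = self.scorers()[q.topic_id].coword_flag
            out[q.topic_id] = {
                self.index.doc_ids[i] for i in np.flatnonzero(flags)
            }
        return out

    def evaluate(self, params="normal", depth: int | None = None) -> EvalSummary:
        if self.qrels is None:
            raise ValueError("evaluation requires qrels")
        runs = self.rank(params, top_k=depth or self.depth)
        return evaluate_run(runs, self.qrels, depth or self.depth,
                            coword_docs=self.coword_documents())

    def objective(self, params="normal") -> float:
        """Avg P@10 + Avg nDCG at the given parameters (the fit target)."""
        if self.qrels is None:
            raise ValueError("the objective requires qrels")
        obj = RetrievalObjective(self.index, self.queries, self.qrels,
                                 mode=self.mode, depth=self.depth)
        return obj.evaluate(self._resolve(params))

    def fit(self, config: CSConfig | None = None, seed: int = 0) -> "CoWordBM25Results":
        """Tune (k1, k3, b1, b2, alpha) by Cuckoo Search; reproducible per seed."""
        if self.qrels is None:
            raise ValueError("fitting requires qrels")
        config = config or CSConfig()
        objective = RetrievalObjective(self.index, self.queries, self.qrels,
                                       mode=self.mode, depth=self.depth)
        result = optimize(objective, config, seed)
        return CoWordBM25Results(self, ModelParams.from_vector(result.best_position),
                                 result, config, seed)


@dataclass
class CoWordBM25Results:
    """Fitted parameters plus optimization and evaluation diagnostics."""

    model: CoWordBM25
    params: ModelParams
    optimize_result: OptimizeResult
    config: CSConfig
    seed: int
    _summary_cache: EvalSummary | None = field(default=None, repr=False)

    @property
    def objective_value(self) -> float:
        return self.optimize_result.best_fitness

    @property
    def trace(self) -> np.ndarray:
        return self.optimize_result.trace

    def params_dict(self) -> dict[str, float]:
        return {name: getattr(self.params, name) for name in _PARAM_NAMES}

    def evaluate(self, depth: int | None = None) -> EvalSummary:
        if self._summary_cache is None:
            self._summary_cache = self.model.evaluate(self.params, depth)
        return self._summary_cache

    def summary(self) -> str:
        """Readable report: fitted vector, bounds, objective, diagnostics."""
        lines = [
            "Co-word BM25 — Cuckoo Search fit",
            "=" * 48,
            f"topics: {len(self.model.queries)}   documents: {len(self.model.index)}"
            f"   mode: {self.model.mode}",
            f"nests: {self.config.n_nests}   generations: {self.config.max_generation}"
            f"   Pa: {self.config.pa}   seed: {self.seed}",
            "-" * 48,
            f"{'param':>8} {'estimate':>12} {'bounds':>18}",
        ]
        for i, name in enumerate(_PARAM_NAMES):
            lines.append(
                f"{name:>8} {getattr(self.params, name):>12.4f} "
                f"{'(%g, %g)' % (self.config.lower[i], self.config.upper[i]):>18}"
            )
        lines += [
            "-" * 48,
            f"objective (Avg P@10 + Avg nDCG): {self.objective_value:.4f}",
            f"objective evaluations: {self.optimize_result.n_evaluations}",
        ]
        ev = self.evaluate()
        lines += [
            f"Avg P@10 = {ev.avg_p10:.4f}   Avg nDCG = {ev.avg_ndcg:.4f}"
            + (f"   Avg cov = {ev.avg_coverage:.4f}" if ev.avg_coverage is not None else ""),
        ]
        return "\n".join(lines)
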