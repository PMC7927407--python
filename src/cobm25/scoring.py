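"""The composite retrieval function: abstract BM25 + expanded-word score +
weighted disease–gene co-word score.

For a query Q and document d the final score is

    Score_composite(Q,d) = Score_abstract(Q,d) + Score_word(Q,d)
                           + alpha * Score_coword(Q,d)

* Score_abstract is Okapi BM25 over the abstract: sum over query morphemes
  q_i of ``log(D/df_i) * f_i (k1+1) / (f_i + K)`` with
  ``K = k1 (1 - b1 + b1 dl/avgdl)``. Query frequencies are 1 by
  construction (duplicates collapse), so the k2 factor is inert.
* Score_word saturates a pseudo-frequency tf_word — the *sum of
  Robertson–Sparck-Jones IDFs* of the query's expanded words present in
  the document's word list — with its own (k3, b2) pair, normalized by the
  word-list length dwl against avgdwl over word-list-bearing documents.
* Score_coword sums, over the query's genes co-occurring with the disease
  in the document, the gene's RSJ IDF. "cross" mode accepts disease and
  gene anywhere in the document's four fields; "within" mode requires them
  inside the same field.

Natural logarithms throughout; the base is a pure scale factor here and
cancels inside nDCG.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np

from .corpus_io import CorpusError, CorpusIndex, CorpusStats, Document, RunEntry, TokenTuple
from .expansion import ExpandedQuery

CowordMode = Literal["cross", "within"]

_FIELD_COUNT = 4  # abstract + chemical + mesh + keyword


@dataclass(frozen=True)
class ModelParams:
    """The tunable parameter vector (k1, k3, b1, b2, alpha); k2 is fixed at 1.

    k1/k3 control term-frequency saturation for the abstract and word-list
    scores, b1/b2 the corresponding length normalizations, and alpha weighs
    the co-word score in the composite.
    """

    k1: float = 1.2
    k3: float = 1.2
    b1: float = 0.75
    b2: float = 0.75
    alpha: float = 1.0
    k2: float = 1.0

    def __post_init__(self):
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError("k1 and k3 must be positive")
        if not (0.0 <= self.b1 <= 1.0 and 0.0 <= self.b2 <= 1.0):
            raise ValueError("b1 and b2 must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.k1, self.k3, self.b1, self.b2, self.alpha])

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "ModelParams":
        k1, k3, b1, b2, alpha = (float(v) for v in vec)
        return cls(k1=k1, k3=k3, b1=b1, b2=b2, alpha=alpha)

    @classmethod
    def preset(cls, name: str) -> "ModelParams":
        """Load a packaged preset: "normal" (classic BM25 defaults) or "cs"
        (the Cuckoo-Search-tuned vector)."""
        ref = resources.files("cobm25").joinpath(f"data/params_{name.lower()}.json")
        if not ref.is_file():
            raise ValueError(f"unknown preset {name!r}")
        return cls(**json.loads(ref.read_text()))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Component scores for one (query, document) pair.

    The decomposition ``composite == abstract + word + alpha*coword`` is
    definitional and holds exactly.
    """

    score_abstract: float
    score_word: float
    score_coword: float
    score_composite: float
    coword_flag: bool


def idf_abstract(term: str, stats: CorpusStats) -> float:
    """log(D / df); out-of-corpus terms are floored at df = 1."""
    if stats.D <= 0:
        raise CorpusError("empty corpus: D = 0")
    df = max(stats.df_abstract.get(term, 0), 1)
    return math.log(stats.D / df)


def relevance_r(f_i: float, dl: float, stats: CorpusStats, params: ModelParams) -> float:
    """BM25 saturation factor f (k1+1) / (f + K), K length-normalized."""
    if f_i <= 0:
        return 0.0
    K = params.k1 * (1.0 - params.b1 + params.b1 * dl / stats.avgdl)
    return f_i * (params.k1 + 1.0) / (f_i + K)


def score_abstract(query: ExpandedQuery, document: Document, index: CorpusIndex,
                   params: ModelParams) -> float:
    i = index.index_of(document.doc_id)
    dl = document.dl
    if dl == 0:
        return 0.0
    total = 0.0
    for term in query.abstract_terms:
        f = index.tf_abstract(term, i)
        if f:
            total += idf_abstract(term, index.stats) * relevance_r(f, dl, index.stats, params)
    return total


def _rsj_idf(N: int, n: int, floor_zero: bool) -> float:
    val = math.log((N - n + 0.5) / (n + 0.5))
    return max(val, 0.0) if floor_zero else val


def idf_word(term_tokens: TokenTuple, stats: CorpusStats,
             floor_zero: bool = False) -> float:
    """RSJ IDF of an expanded word over word-list-bearing documents.

    May be negative when the word occurs in more than half of those
    documents; negatives are preserved unless ``floor_zero``.
    """
    if stats.n_wordlist == 0:
        raise CorpusError("no word-list documents (n_wordlist = 0)")
    n = stats.df_wordlist.get(" ".join(term_tokens), 0)
    return _rsj_idf(stats.n_wordlist, n, floor_zero)


def tf_word(query: ExpandedQuery, document: Document, index: CorpusIndex,
            floor_zero: bool = False) -> float:
    """Pseudo-frequency of the word list: sum of IDFs of matching expanded words."""
    if index.stats.n_wordlist == 0 or document.dwl == 0:
        return 0.0
    i = index.index_of(document.doc_id)
    return sum(
        idf_word(t, index.stats, floor_zero)
        for t in query.wordlist_terms
        if index.wordlist_contains(t, i)
    )


def score_word(query: ExpandedQuery, document: Document, index: CorpusIndex,
               params: ModelParams, floor_zero: bool = False) -> float:
    tf = tf_word(query, document, index, floor_zero)
    if tf == 0.0:
        return 0.0
    denom_k = params.k3 * (
        1.0 - params.b2 + params.b2 * document.dwl / index.stats.avgdwl
    )
    return tf * (params.k3 + 1.0) / (tf + denom_k)


def _term_in_field(term: TokenTuple, field_terms: Sequence[TokenTuple]) -> bool:
    n = len(term)
    for ft in field_terms:
        if any(ft[i:i + n] == term for i in range(len(ft) - n + 1)):
            return True
    return False


def _term_in_abstract(term: TokenTuple, abstract: tuple[str, ...]) -> bool:
    n = len(term)
    return any(abstract[i:i + n] == term for i in range(len(abstract) - n + 1))


def _presence_vector(term: TokenTuple, document: Document) -> list[bool]:
    """Per-field presence: [abstract, chemical, mesh, keyword]."""
    return [
        _term_in_abstract(term, document.abstract_tokens),
        _term_in_field(term, document.chemical_tokens),
        _term_in_field(term, document.mesh_tokens),
        _term_in_field(term, document.keyword_tokens),
    ]


def detect_coword(document: Document, disease_terms: Sequence[TokenTuple],
                  gene_terms: Sequence[TokenTuple],
                  mode: CowordMode = "cross") -> set[TokenTuple]:
    """Genes of the query co-occurring with its disease in the document.

    "cross": disease anywhere in the four fields and gene anywhere in the
    four fields. "within": disease and gene inside the same field. Matching
    is contiguous token-subsequence matching on normalized terms; substrings
    of a token never match (RAS does not match KRAS).
    """
    if mode not in ("cross", "within"):
        raise ValueError(f"unknown co-word mode {mode!r}")
    disease_presence = [False] * _FIELD_COUNT
    for dterm in disease_terms:
        for f, hit in enumerate(_presence_vector(dterm, document)):
            disease_presence[f] = disease_presence[f] or hit
    if not any(disease_presence):
        return set()
    matched: set[TokenTuple] = set()
    for gene in gene_terms:
        gp = _presence_vector(gene, document)
        if mode == "cross":
            if any(gp):
                matched.add(gene)
        else:
            if any(d and g for d, g in zip(disease_presence, gp)):
                matched.add(gene)
    return matched


def idf_gene(gene: TokenTuple, index: CorpusIndex, use_wordlist_n: bool = False,
             floor_zero: bool = False) -> float:
    """RSJ IDF of a gene morpheme; N defaults to the full corpus size."""
    N = index.stats.n_wordlist if use_wordlist_n else index.stats.D
    n = index.df_anywhere(gene)
    return _rsj_idf(N, n, floor_zero)


def score_coword(query: ExpandedQuery, document: Document, index: CorpusIndex,
                 mode: CowordMode = "cross", use_wordlist_n: bool = False,
                 floor_zero: bool = False) -> float:
    matched = detect_coword(document, query.disease_terms, query.gene_terms, mode)
    return sum(idf_gene(g, index, use_wordlist_n, floor_zero) for g in matched)


def score_composite(query: ExpandedQuery, document: Document, index: CorpusIndex,
                    params: ModelParams, mode: CowordMode = "cross",
                    use_wordlist_n: bool = False,
                    floor_zero: bool = False) -> ScoreBreakdown:
    sa = score_abstract(query, document, index, params)
    sw = score_word(query, document, index, params, floor_zero)
    matched = detect_coword(document, query.disease_terms, query.gene_terms, mode)
    sc = sum(idf_gene(g, index, use_wordlist_n, floor_zero) for g in matched)
    return ScoreBreakdown(
        score_abstract=sa,
        score_word=sw,
        score_coword=sc,
        score_composite=sa + sw + params.alpha * sc,
        coword_flag=bool(matched),
    )


class QueryScorer:
    """Vectorized scorer for one expanded query over a whole index.

    All parameter-independent quantities — per-term abstract postings and
    IDFs, the word-list pseudo-frequency tf_word, and the co-word score —
    are precomputed once, so re-scoring under new parameters (as the
    optimizer does thousands of times) costs a handful of numpy
    operations.
    """

    def __init__(self, query: ExpandedQuery, index: CorpusIndex,
                 mode: CowordMode = "cross", use_wordlist_n: bool = False,
                 floor_zero: bool = False):
        self.query = query
        self.index = index
        self.mode = mode
        stats = index.stats
        D = stats.D
        self.dl = np.array([d.dl for d in index.documents], dtype=float)
        self.dwl = np.array([d.dwl for d in index.documents], dtype=float)

        # abstract: one (idf, doc-index array, tf array) triple per term
        self._abstract_terms = []
        for term in query.abstract_terms:
            post = index.postings_abstract(term)
            if not post:
                continue
            idx = np.fromiter(post.keys(), dtype=np.intp, count=len(post))
            tf = np.fromiter(post.values(), dtype=float, count=len(post))
            self._abstract_terms.append((idf_abstract(term, stats), idx, tf))

        # word list: tf_word is parameter-free
        self.tf_w = np.zeros(D)
        if stats.n_wordlist > 0:
            for t in query.wordlist_terms:
                docs = index.wordlist_doc_indices(t)
                if docs:
                    w = idf_word(t, stats, floor_zero)
                    self.tf_w[np.fromiter(docs, dtype=np.intp, count=len(docs))] += w

        # co-word score and flag, also parameter-free
        self.coword = np.zeros(D)
        self.coword_flag = np.zeros(D, dtype=bool)
        for i, doc in enumerate(index.documents):
            matched = detect_coword(doc, query.disease_terms, query.gene_terms, mode)
            if matched:
                self.coword_flag[i] = True
                self.coword[i] = sum(
                    idf_gene(g, index, use_wordlist_n, floor_zero) for g in matched
                )

    def component_scores(self, params: ModelParams):
        """(abstract, word, coword) score arrays over all documents."""
        stats = self.index.stats
        sa = np.zeros(len(self.dl))
        K = params.k1 * (1.0 - params.b1 + params.b1 * self.dl / stats.avgdl)
        for idf, idx, tf in self._abstract_terms:
            sa[idx] += idf * tf * (params.k1 + 1.0) / (tf + K[idx])
        sw = np.zeros_like(sa)
        nz = self.tf_w != 0.0
        if nz.any() and stats.avgdwl > 0:
            denom_k = params.k3 * (1.0 - params.b2 + params.b2 * self.dwl[nz] / stats.avgdwl)
            sw[nz] = self.tf_w[nz] * (params.k3 + 1.0) / (self.tf_w[nz] + denom_k)
        return sa, sw, self.coword

    def composite_scores(self, params: ModelParams) -> np.ndarray:
        sa, sw, sc = self.component_scores(params)
        return sa + sw + params.alpha * sc

    def rank(self, params: ModelParams, top_k: int = 1000,
             tag: str = "cobm25") -> list[RunEntry]:
        """Top-k documents by composite score; ties break on ascending doc_id."""
        scores = self.composite_scores(params)
        order = sorted(range(len(scores)),
                       key=lambda i: (-scores[i], self.index.doc_ids[i]))[:top_k]
        return [
            RunEntry(self.query.topic_id, self.index.doc_ids[i], r + 1,
                     float(scores[i]), tag)
            for r, i in enumerate(order)
        ]


def rank_corpus(query: ExpandedQuery, index: CorpusIndex, params: ModelParams,
                mode: CowordMode = "cross", top_k: int = 1000,
                tag: str = "cobm25", **kw) -> list[RunEntry]:
    """Rank the whole corpus for one query (convenience over QueryScorer)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    return QueryScorer(query, index, mode=mode, **kw).rank(params, top_k, tag)
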