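"""Cuckoo Search with Lévy flights for tuning the retrieval parameters.

The metaheuristic maintains n "nests" (candidate parameter vectors).
Each generation every nest emits a cuckoo egg displaced by a heavy-tailed
Lévy-flight step, X(t+1) = X(t) + T (+) Levy(lambda); the egg replaces a
randomly chosen nest only if fitter (greedy replacement). Each non-best
nest is then abandoned with probability Pa and redrawn uniformly inside
the bounds; the best nest is always handed down, so the best-so-far
fitness trace is monotone non-decreasing.

Lévy steps use Mantegna's construction: s = u / |v|^(1/beta) with
u ~ N(0, sigma_u^2), v ~ N(0, 1). Following the origin method's reference
implementation, the raw step is scaled by 0.01 times the displacement from
the current best nest, which lets step sizes shrink as the swarm
converges; with T = 0 proposals leave positions unchanged.

The retrieval objective is Avg P@10 + Avg nDCG over the training topics
(in [0, 2]); :class:`RetrievalObjective` precomputes per-topic scorers so
one evaluation costs a few numpy operations per topic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus_io import CorpusIndex, Qrels
from .evaluation import _gain
from .expansion import ExpandedQuery
from .scoring import CowordMode, ModelParams, QueryScorer

Vector = np.ndarray


def table5_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Search-space bounds for (k1, k3, b1, b2, alpha): (0,100)^2 x (0,1)^2 x (0,5).

    The intervals are open at 0; a tiny positive floor keeps k1/k3 valid.
    """
    lower = np.array([1e-6, 1e-6, 0.0, 0.0, 0.0])
    upper = np.array([100.0, 100.0, 1.0, 1.0, 5.0])
    return lower, upper


@dataclass
class CSConfig:
    """Cuckoo Search settings (population, step size, bounds, abandonment)."""

    n_nests: int = 40
    step_size: float = 1.0
    max_generation: int = 500
    pa: float = 0.25
    levy_lambda: float = 1.5
    lower: np.ndarray = field(default_factory=lambda: table5_bounds()[0])
    upper: np.ndarray = field(default_factory=lambda: table5_bounds()[1])
    boundary: str = "clamp"  # or "reflect"

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.n_nests < 2:
            raise ValueError("need at least 2 nests")
        if self.step_size < 0:
            raise ValueError("step size T must be >= 0")
        if not (0.0 < self.pa < 1.0):
            raise ValueError("Pa must lie in (0, 1)")
        if self.lower.shape != self.upper.shape or np.any(self.lower >= self.upper):
            raise ValueError("infeasible bounds: require lower < upper per dimension")
        if self.boundary not in ("clamp", "reflect"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class CSState:
    """Nest positions and fitness values at one generation (maximization)."""

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    generation: int = 0


def levy_step(dimension: int, lambda_exponent: float, rng: np.random.Generator) -> np.ndarray:
    """A Lévy-flight displacement vector via Mantegna's algorithm.

    Valid for lambda in (1, 3]; for lambda >= 2 the stable distribution
    degenerates to Gaussian steps.
    """
    if not (1.0 < lambda_exponent <= 3.0):
        raise ValueError(f"Levy exponent must lie in (1, 3], got {lambda_exponent}")
    if dimension == 0:
        return np.zeros(0)
    beta = lambda_exponent
    if beta >= 2.0:
        return rng.standard_normal(dimension)
    sigma_u = (
        math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=dimension)
    v = rng.standard_normal(dimension)
    return u / np.abs(v) ** (1.0 / beta)


def _apply_bounds(x: np.ndarray, config: CSConfig) -> np.ndarray:
    if config.boundary == "reflect":
        span = config.upper - config.lower
        y = np.mod(x - config.lower, 2 * span)
        y = np.where(y > span, 2 * span - y, y)
        return config.lower + y
    return np.clip(x, config.lower, config.upper)


def propose(position: np.ndarray, best_position: np.ndarray, config: CSConfig,
            rng: np.random.Generator) -> np.ndarray:
    """One Lévy-flight proposal from ``position``, kept inside the bounds."""
    step = levy_step(config.dim, config.levy_lambda, rng)
    scale = position - best_position
    if not np.any(scale):
        scale = config.upper - config.lower
    new = position + config.step_size * 0.01 * step * scale
    return _apply_bounds(new, config)


def abandon_worst(state: CSState, pa: float, rng: np.random.Generator,
                  config: CSConfig) -> list[int]:
    """Abandon each non-best nest with probability Pa.

    Replaced nests get fresh uniform positions and NaN fitness (the caller
    re-evaluates); the nest count never changes and the best nest is never
    abandoned. Returns the replaced indices.
    """
    best_idx = int(np.argmax(state.fitness))
    replaced: list[int] = []
    for i in range(state.positions.shape[0]):
        if i == best_idx:
            continue
        if rng.random() < pa:
            state.positions[i] = rng.uniform(config.lower, config.upper)
            state.fitness[i] = np.nan
            replaced.append(i)
    return replaced


@dataclass
class OptimizeResult:
    """Outcome of a Cuckoo Search run."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # per-generation best-so-far fitness
    n_evaluations: int
    state: CSState


class _CachedObjective:
    """Memoizes a deterministic objective on 1e-9-quantized vectors."""

    def __init__(self, fn: Callable[[np.ndarray], float]):
        self.fn = fn
        self.cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def __call__(self, x: np.ndarray) -> float:
        key = tuple(np.round(np.asarray(x, dtype=float) / 1e-9).astype(np.int64))
        if key not in self.cache:
            self.cache[key] = float(self.fn(x))
            self.n_evaluations += 1
        return self.cache[key]


def optimize(objective: Callable[[np.ndarray], float], config: CSConfig,
             seed: int | np.random.Generator = 0) -> OptimizeResult:
    """Maximize ``objective`` over the configured box by Cuckoo Search.

    Fully reproducible for a fixed seed; the returned trace (best-so-far
    fitness per generation, including the initial population) is monotone
    non-decreasing by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obj = _CachedObjective(objective)

    positions = rng.uniform(config.lower, config.upper, size=(config.n_nests, config.dim))
    fitness = np.array([obj(p) for p in positions])
    best_idx = int(np.argmax(fitness))
    state = CSState(
        positions=positions,
        fitness=fitness,
        best_position=positions[best_idx].copy(),
        best_fitness=float(fitness[best_idx]),
    )
    trace = [state.best_fitness]

    for gen in range(1, config.max_generation + 1):
        # each cuckoo lays one egg; it replaces a random nest if fitter
        for i in range(config.n_nests):
            egg = propose(state.positions[i], state.best_position, config, rng)
            f_egg = obj(egg)
            j = int(rng.integers(config.n_nests))
            if f_egg > state.fitness[j]:
                state.positions[j] = egg
                state.fitness[j] = f_egg
        # abandon discovered nests (never the best one)
        for i in abandon_worst(state, config.pa, rng, config):
            state.fitness[i] = obj(state.positions[i])
        gen_best = int(np.argmax(state.fitness))
        if state.fitness[gen_best] > state.best_fitness:
            state.best_fitness = float(state.fitness[gen_best])
            state.best_position = state.positions[gen_best].copy()
        state.generation = gen
        trace.append(state.best_fitness)

    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        trace=np.array(trace),
        n_evaluations=obj.n_evaluations,
        state=state,
    )


class RetrievalObjective:
    """Avg P@10 + Avg nDCG of the composite ranking, as a function of the
    parameter vector (k1, k3, b1, b2, alpha).

    Per-topic scorers, relevance-grade arrays and ideal DCGs are
    precomputed, so each call reduces to vectorized rescoring plus a sort.
    """

    def __init__(self, index: CorpusIndex, queries: Sequence[ExpandedQuery],
                 qrels: Qrels, mode: CowordMode = "cross", depth: int = 1000,
                 exponential_gain: bool = False):
        if not queries:
            raise ValueError("no topics to evaluate")
        self.depth = depth
        self.topics: list[dict] = []
        # stable tie-break identical to rank_corpus: ascending doc_id
        tie_rank = np.argsort(np.argsort(np.array(index.doc_ids)))
        for q in queries:
            scorer = QueryScorer(q, index, mode=mode)
            judged = qrels.judged(q.topic_id)
            grades = np.array(
                [qrels.grade(q.topic_id, d) for d in index.doc_ids], dtype=float
            )
            gains = np.array([_gain(int(g), exponential_gain) for g in grades])
            ideal = sorted(
                (_gain(g, exponential_gain) for g in judged.values()), reverse=True
            )[:depth]
            dcg_i = sum(g / math.log(i + 2) for i, g in enumerate(ideal) if g > 0)
            self.topics.append({
                "scorer": scorer, "grades": grades, "gains": gains,
                "dcg_i": dcg_i, "tie": tie_rank,
            })
        self._discount = 1.0 / np.log(np.arange(depth) + 2.0)

    def __call__(self, vec: np.ndarray) -> float:
        params = ModelParams.from_vector(vec)
        return self.evaluate(params)

    def evaluate(self, params: ModelParams) -> float:
        p10_sum = 0.0
        ndcg_sum = 0.0
        for t in self.topics:
            scores = t["scorer"].composite_scores(params)
            order = np.lexsort((t["tie"], -scores))[:self.depth]
            top_grades = t["grades"][order]
            p10_sum += float(np.count_nonzero(top_grades[:10] >= 1)) / 10.0
            if t["dcg_i"] > 0:
                gains = t["gains"][order]
                ndcg_sum += float(gains @ self._discount[:gains.size]) / t["dcg_i"]
        n = len(self.topics)
        return p10_sum / n + ndcg_sum / n


def optimize_retrieval(index: CorpusIndex, queries: Sequence[ExpandedQuery],
                       qrels: Qrels, config: CSConfig | None = None,
                       seed: int = 0, mode: CowordMode = "cross",
                       depth: int = 1000) -> tuple[ModelParams, OptimizeResult]:
    """Tune (k1, k3, b1, b2, alpha) on a training collection."""
    config = config or CSConfig()
    objective = RetrievalObjective(index, queries, qrels, mode=mode, depth=depth)
    result = optimize(objective, config, seed)
    return ModelParams.from_vector(result.best_position), result
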