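"""Lattice-search strategies: exhaustive oracle, greedy best-first (bottom-up
and top-down), and a two-subpopulation genetic algorithm.

Every strategy optimizes the same fitness: the granularity quality of the
output *after* records have been suppressed to satisfy the privacy model, so
a scheme that forces heavy suppression scores poorly even if it generalizes
little.  Ties are broken everywhere by the lexicographically smallest level
vector, which makes all searches deterministic given a seed.

The evaluation context pre-encodes, per quasi-identifier and per level, each
record's generalized value as an integer code together with its granularity
loss.  A scheme evaluation then reduces to integer column combination, a
``bincount`` over class ids, and a masked loss sum — no string handling.
"""

from __future__ import annotations

import heapq
import itertools
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_model import Dataset, Lattice, Scheme, neighbors
from .privacy import (KAnonymity, PopulationUniqueness, PrivacyModel,
                      estimate_population_uniqueness)
from .transform import (EquivalenceClassHistogram, TransformedDataset,
                        apply_scheme, quality_granularity, suppress_to_satisfy)

__all__ = [
    "SearchBudget",
    "GAConfig",
    "Individual",
    "TracePoint",
    "SearchTrace",
    "AnonymizationResult",
    "AnonymizationContext",
    "evaluate_scheme",
    "search_exhaustive",
    "search_greedy",
    "search_genetic",
    "triangle_init",
    "next_generation",
    "run_search",
]

EXHAUSTIVE_CAP = 100_000


@dataclass(frozen=True)
class SearchBudget:
    """Evaluation/time bounds; checked between individual scheme evaluations."""

    time_limit: float | None = None
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        if self.time_limit is not None and self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.max_evaluations is not None and self.max_evaluations < 1:
            raise ValueError("max_evaluations must be >= 1")

    @property
    def unbounded(self) -> bool:
        return self.time_limit is None and self.max_evaluations is None


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm parameters.

    Defaults are the parameterization used by the benchmarked tool: elite,
    crossover, production and immigration fractions of 0.2/0.4/0.2/0.2, a
    mutation probability of 0.05 (upper bound on the changed-gene fraction),
    immigration every 10 iterations, 50 iterations, and two subpopulations of
    50 individuals each.
    """

    elite_fraction: float = 0.2
    crossover_fraction: float = 0.4
    production_fraction: float = 0.2
    mutation_probability: float = 0.05
    immigration_fraction: float = 0.2
    immigration_interval: int = 10
    iterations: int = 50
    subpopulation_size: int = 50

    def __post_init__(self) -> None:
        for name in ("elite_fraction", "crossover_fraction", "production_fraction",
                     "mutation_probability", "immigration_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.elite_fraction + self.crossover_fraction > 1.0:
            raise ValueError("elite_fraction + crossover_fraction must be <= 1")
        if self.subpopulation_size < 2:
            raise ValueError("subpopulation_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.immigration_interval < 1:
            raise ValueError("immigration_interval must be >= 1")

    @property
    def n_elite(self) -> int:
        return max(1, _round_half_up(self.elite_fraction * self.subpopulation_size))

    @property
    def n_crossover(self) -> int:
        return _round_half_up(self.crossover_fraction * self.subpopulation_size)

    @property
    def n_producers(self) -> int:
        return max(2, _round_half_up(self.production_fraction * self.subpopulation_size))

    @property
    def n_immigrants(self) -> int:
        return _round_half_up(self.immigration_fraction * self.subpopulation_size)

    def mutation_bound(self, n_genes: int) -> int:
        return max(1, _round_half_up(self.mutation_probability * n_genes))


@dataclass
class Individual:
    """A candidate generalization scheme with its (lazily computed) fitness."""

    genes: Scheme
    fitness: float | None = None


@dataclass(frozen=True)
class TracePoint:
    elapsed: float
    evaluations: int
    best_quality: float
    best_scheme: Scheme


SearchTrace = list[TracePoint]


@dataclass
class AnonymizationResult:
    """Outcome of a search: best scheme(s), output data, score, and trace."""

    algorithm: str
    scheme: Scheme | None
    quality: float
    transformed: TransformedDataset | None
    n_suppressed: int
    evaluations: int
    elapsed: float
    trace: SearchTrace = field(default_factory=list)


class BudgetExhausted(Exception):
    pass


class AnonymizationContext:
    """Dataset + privacy model + quality model, with memoized scheme evaluation.

    ``evaluate`` returns the post-suppression granularity quality (percent)
    of a scheme using the pre-encoded integer fast path; ``materialize``
    rebuilds the full string-valued :class:`TransformedDataset` through the
    transform layer (the two routes are asserted equivalent in the tests).
    """

    def __init__(self, dataset: Dataset, model: PrivacyModel,
                 suppression_token: str = "*"):
        self.dataset = dataset
        self.model = model
        self.suppression_token = suppression_token
        self.lattice = Lattice(dataset.heights)
        self._cache: dict[Scheme, tuple[float, int]] = {}
        self.evaluations = 0
        self._start = time.perf_counter()
        self._budget: SearchBudget | None = None
        self._trace: SearchTrace = []
        self._best: tuple[float, Scheme] | None = None
        self._encode()

    def _encode(self) -> None:
        qi = self.dataset.quasi_identifiers
        n = self.dataset.n_records
        self._codes: list[list[np.ndarray]] = []
        self._cards: list[list[int]] = []
        self._losses: list[list[np.ndarray]] = []
        for attr in qi:
            hier = attr.hierarchy
            assert hier is not None
            raw = self.dataset.frame[attr.name].to_numpy()
            per_level_codes, per_level_cards, per_level_loss = [], [], []
            D = hier.n_leaves
            for level in range(hier.height + 1):
                mapping = hier.mapping(level)
                values = sorted(set(mapping.values()))
                value_code = {v: c for c, v in enumerate(values)}
                try:
                    codes = np.fromiter((value_code[mapping[x]] for x in raw),
                                        dtype=np.int64, count=n)
                except KeyError as exc:
                    raise KeyError(
                        f"value {exc.args[0]!r} of attribute {attr.name!r} "
                        f"is not a hierarchy leaf") from None
                if D > 1:
                    loss_by_code = np.array(
                        [(hier.leaf_count(v, level) - 1) / (D - 1) for v in values])
                    loss = loss_by_code[codes]
                else:
                    loss = np.zeros(n)
                per_level_codes.append(codes)
                per_level_cards.append(len(values))
                per_level_loss.append(loss)
            self._codes.append(per_level_codes)
            self._cards.append(per_level_cards)
            self._losses.append(per_level_loss)

    # -- timing / budget -------------------------------------------------
    def start_clock(self, budget: SearchBudget | None) -> None:
        self._budget = budget
        self._start = time.perf_counter()

    @property
    def elapsed(self) -> float:
        return time.perf_counter() - self._start

    def _check_budget(self) -> None:
        b = self._budget
        if b is None:
            return
        if b.max_evaluations is not None and self.evaluations >= b.max_evaluations:
            raise BudgetExhausted
        if b.time_limit is not None and self.elapsed >= b.time_limit:
            raise BudgetExhausted

    # -- evaluation ------------------------------------------------------
    def _class_ids(self, scheme: Scheme) -> tuple[np.ndarray, np.ndarray]:
        """Return (class id per record, class sizes)."""
        n = self.dataset.n_records
        combined = np.zeros(n, dtype=np.int64)
        card = 1
        for i, g in enumerate(scheme):
            ci = self._cards[i][g]
            if card * ci > (1 << 62):
                _, combined = np.unique(combined, return_inverse=True)
                card = int(combined.max()) + 1 if n else 1
            combined = combined * ci + self._codes[i][g]
            card *= ci
        _, ids, counts = np.unique(combined, return_inverse=True, return_counts=True)
        return ids, counts

    def _suppression_mask(self, scheme: Scheme) -> np.ndarray:
        """Boolean mask of records suppressed to satisfy the privacy model."""
        n = self.dataset.n_records
        if n == 0:
            return np.zeros(0, dtype=bool)
        ids, counts = self._class_ids(scheme)
        if isinstance(self.model, KAnonymity):
            return counts[ids] < self.model.k
        # population uniqueness: drop whole classes, smallest first
        # (ties by first occurrence), until the estimate meets the threshold
        model = self.model
        first_idx = np.full(len(counts), n, dtype=np.int64)
        np.minimum.at(first_idx, ids, np.arange(n))
        order = np.lexsort((first_idx, counts))
        size_counter = Counter(int(c) for c in counts)
        mask = np.zeros(n, dtype=bool)
        removed = 0
        while True:
            sizes = tuple(size_counter.elements())
            if not sizes:
                break
            hist = EquivalenceClassHistogram(sizes)
            if estimate_population_uniqueness(
                    hist, model.sampling_fraction) <= model.threshold:
                break
            cls = int(order[removed])
            mask |= ids == cls
            size_counter[int(counts[cls])] -= 1
            removed += 1
        return mask

    def _evaluate_raw(self, scheme: Scheme) -> tuple[float, int]:
        n = self.dataset.n_records
        m = len(scheme)
        if n == 0 or m == 0:
            return 100.0, 0
        mask = self._suppression_mask(scheme)
        n_sup = int(mask.sum())
        loss = float(sum(self._losses[i][g][~mask].sum()
                         for i, g in enumerate(scheme)))
        loss += n_sup * m
        return 100.0 * (1.0 - loss / (n * m)), n_sup

    def evaluate(self, scheme: Scheme) -> float:
        """Memoized post-suppression quality (percent) of a scheme.

        Raises :class:`BudgetExhausted` if the budget ran out *before* this
        evaluation (a single evaluation is never interrupted).
        """
        scheme = tuple(scheme)
        hit = self._cache.get(scheme)
        if hit is not None:
            return hit[0]
        self._check_budget()
        quality, n_sup = self._evaluate_raw(scheme)
        self._cache[scheme] = (quality, n_sup)
        self.evaluations += 1
        if self._best is None or (-quality, scheme) < (-self._best[0], self._best[1]):
            self._best = (quality, scheme)
        self._trace.append(TracePoint(self.elapsed, self.evaluations,
                                      self._best[0], self._best[1]))
        return quality

    def n_suppressed(self, scheme: Scheme) -> int:
        self.evaluate(scheme)
        return self._cache[tuple(scheme)][1]

    def materialize(self, scheme: Scheme) -> TransformedDataset:
        """Full string-valued output for a scheme (transform-layer path)."""
        t = apply_scheme(self.dataset, scheme, self.suppression_token)
        return suppress_to_satisfy(t, self.model)

    def result(self, algorithm: str) -> AnonymizationResult:
        assert self._best is not None, "no scheme was evaluated"
        quality, scheme = self._best
        transformed = self.materialize(scheme)
        return AnonymizationResult(
            algorithm=algorithm, scheme=scheme, quality=quality,
            transformed=transformed, n_suppressed=transformed.n_suppressed,
            evaluations=self.evaluations, elapsed=self.elapsed,
            trace=list(self._trace))


def evaluate_scheme(ctx: AnonymizationContext,
                    scheme: Scheme) -> tuple[float, TransformedDataset]:
    """Quality and transformed output of one scheme (memoized within ``ctx``)."""
    quality = ctx.evaluate(scheme)
    return quality, ctx.materialize(scheme)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def search_exhaustive(ctx: AnonymizationContext,
                      cap: int = EXHAUSTIVE_CAP) -> AnonymizationResult:
    """Evaluate every scheme; return the maximum-quality one.

    Ties go to the lexicographically smallest level vector.  Refuses lattices
    larger than ``cap`` (use a heuristic there instead).
    """
    lattice = ctx.lattice
    if lattice.size > cap:
        raise ValueError(
            f"lattice size {lattice.size} exceeds the exhaustive cap {cap}; "
            f"use a heuristic search (bottom_up, top_down, genetic)")
    ctx.start_clock(None)
    for scheme in lattice.schemes():
        ctx.evaluate(scheme)
    return ctx.result("exhaustive")


# ---------------------------------------------------------------------------
# greedy best-first
# ---------------------------------------------------------------------------

def search_greedy(ctx: AnonymizationContext, direction: str = "bottom_up",
                  budget: SearchBudget | None = None) -> AnonymizationResult:
    """Greedy best-first search from the bottom (or top) of the lattice.

    Repeatedly expands the best-quality not-yet-expanded scheme by evaluating
    its immediate up-neighbors (bottom-up) or down-neighbors (top-down).  Run
    to exhaustion it visits the whole lattice and therefore returns the
    exhaustive optimum; under a budget it returns the incumbent best.
    """
    if direction not in ("bottom_up", "top_down"):
        raise ValueError("direction must be 'bottom_up' or 'top_down'")
    lattice = ctx.lattice
    start = lattice.bottom if direction == "bottom_up" else lattice.top
    step = "up" if direction == "bottom_up" else "down"
    ctx.start_clock(budget)
    frontier: list[tuple[float, Scheme]] = []
    seen: set[Scheme] = set()
    try:
        q = ctx.evaluate(start)
        heapq.heappush(frontier, (-q, start))
        seen.add(start)
        while frontier:
            _, scheme = heapq.heappop(frontier)
            for nb in neighbors(scheme, lattice, step):
                if nb in seen:
                    continue
                seen.add(nb)
                qn = ctx.evaluate(nb)
                heapq.heappush(frontier, (-qn, nb))
    except BudgetExhausted:
        pass
    return ctx.result(direction)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def triangle_init(heights: Sequence[int], count: int) -> list[Scheme]:
    """Deterministic triangle-pattern seed schemes.

    Row ``j`` raises the first ``j`` attributes to their maximum levels and
    leaves the rest at 0, giving a staircase from the all-zero scheme to the
    all-maximum scheme; at most ``count`` rows are produced.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    m = len(heights)
    rows = min(m + 1, count)
    out = []
    for j in range(rows):
        out.append(tuple(heights[i] if i < j else 0 for i in range(m)))
    return out


def _sort_key(ind: Individual) -> tuple[float, Scheme]:
    assert ind.fitness is not None
    return (-ind.fitness, ind.genes)


def next_generation(subpop: list[Individual], cfg: GAConfig,
                    rng: np.random.Generator, heights: Sequence[int],
                    evaluate: Callable[[Scheme], float]) -> list[Individual]:
    """Produce the next generation of one subpopulation.

    Fittest-first sort (ties: lexicographically smallest genes); the elite
    fraction is copied unchanged; the crossover fraction is bred from two
    distinct parents drawn from the production fraction with rank-linear
    weights, each gene inherited from a uniformly chosen parent; the rest are
    mutants of uniformly chosen individuals with between 1 and the mutation
    bound genes resampled uniformly over their full level range.
    """
    s = cfg.subpopulation_size
    if len(subpop) != s:
        raise ValueError(f"subpopulation size {len(subpop)} != {s}")
    for ind in subpop:
        if ind.fitness is None:
            ind.fitness = evaluate(ind.genes)
    ranked = sorted(subpop, key=_sort_key)
    e, c, p = cfg.n_elite, cfg.n_crossover, cfg.n_producers
    nxt: list[Individual] = [Individual(ind.genes, ind.fitness)
                             for ind in ranked[:e]]
    m = len(heights)
    producers = ranked[:min(p, s)]
    weights = np.arange(len(producers), 0, -1, dtype=np.float64)
    weights /= weights.sum()
    for _ in range(min(c, s - e)):
        i = int(rng.choice(len(producers), p=weights))
        w2 = weights.copy()
        w2[i] = 0.0
        w2 /= w2.sum()
        j = int(rng.choice(len(producers), p=w2))
        pa, pb = producers[i].genes, producers[j].genes
        pick = rng.integers(0, 2, size=m)
        child = tuple(pa[g] if pick[g] == 0 else pb[g] for g in range(m))
        nxt.append(Individual(child))
    bound = cfg.mutation_bound(m)
    while len(nxt) < s:
        base = ranked[int(rng.integers(0, s))].genes
        n_mut = int(rng.integers(1, bound + 1))
        n_mut = min(n_mut, m)
        sites = rng.choice(m, size=n_mut, replace=False)
        genes = list(base)
        for site in sites:
            genes[site] = int(rng.integers(0, heights[site] + 1))
        nxt.append(Individual(tuple(genes)))
    for ind in nxt:
        if ind.fitness is None:
            ind.fitness = evaluate(ind.genes)
    return nxt


def search_genetic(ctx: AnonymizationContext, cfg: GAConfig | None = None,
                   budget: SearchBudget | None = None,
                   seed: int = 0) -> AnonymizationResult:
    """Two-subpopulation genetic search.

    Subpopulation 1 is seeded with the triangle pattern and filled with
    uniform-random schemes; subpopulation 2 is fully random.  Each iteration
    advances both via :func:`next_generation`; every ``immigration_interval``
    iterations the fittest individuals of each subpopulation (pre-swap state)
    replace the weakest of the other.  The incumbent best over *all* evaluated
    schemes is returned.
    """
    cfg = cfg or GAConfig()
    heights = ctx.lattice.heights
    rng = np.random.default_rng(seed)
    s = cfg.subpopulation_size
    ctx.start_clock(budget)

    def random_scheme() -> Scheme:
        return tuple(int(rng.integers(0, h + 1)) for h in heights)

    tri = triangle_init(heights, s)
    pop1 = [Individual(g) for g in tri]
    pop1 += [Individual(random_scheme()) for _ in range(s - len(pop1))]
    pop2 = [Individual(random_scheme()) for _ in range(s)]

    try:
        for pop in (pop1, pop2):
            for ind in pop:
                ind.fitness = ctx.evaluate(ind.genes)
        for iteration in range(1, cfg.iterations + 1):
            pop1 = next_generation(pop1, cfg, rng, heights, ctx.evaluate)
            pop2 = next_generation(pop2, cfg, rng, heights, ctx.evaluate)
            if iteration % cfg.immigration_interval == 0 and cfg.n_immigrants > 0:
                k = min(cfg.n_immigrants, s)
                r1 = sorted(pop1, key=_sort_key)
                r2 = sorted(pop2, key=_sort_key)
                top1 = [Individual(i.genes, i.fitness) for i in r1[:k]]
                top2 = [Individual(i.genes, i.fitness) for i in r2[:k]]
                pop1 = r1[:s - k] + top2
                pop2 = r2[:s - k] + top1
    except BudgetExhausted:
        pass
    return ctx.result("genetic")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def run_search(ctx: AnonymizationContext, algorithm: str,
               budget: SearchBudget | None = None,
               ga_config: GAConfig | None = None, seed: int = 0,
               exhaustive_cap: int = EXHAUSTIVE_CAP) -> AnonymizationResult:
    """Run the named algorithm (``exhaustive | bottom_up | top_down | genetic``)."""
    if algorithm == "exhaustive":
        return search_exhaustive(ctx, cap=exhaustive_cap)
    if algorithm in ("bottom_up", "top_down"):
        return search_greedy(ctx, direction=algorithm, budget=budget)
    if algorithm == "genetic":
        return search_genetic(ctx, cfg=ga_config, budget=budget, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")
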