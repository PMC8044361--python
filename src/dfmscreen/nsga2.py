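"""Elitist NSGA-II over fixed-length ternary genomes.

Self-contained implementation of the non-dominated sorting genetic
algorithm: Pareto dominance, fast non-dominated sorting, crowding distance,
crowded-comparison tournament selection, half-uniform crossover (HUX) and
per-position flip mutation, run as a generational loop that merges the
current population with an elite archive E of all non-dominated individuals
found so far. All objectives are minimized; callers maximizing an objective
negate it before handing the evaluator over.

The loop bookkeeping deviates from the canonical parent+offspring (mu+lambda)
merge: each generation merges P with the archive E instead. E can only
improve (its dominated region never shrinks), so elitism is preserved; with
the initial population counted as generation 1 the evaluation budget is
exactly Q x IT_max evaluator calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "OptimizerConfig",
    "NSGAResult",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "crowded_compare",
    "hux_crossover",
    "flip_mutation",
    "run",
]

Genome = tuple[int, ...]
Fitness = tuple[float, ...]
Evaluator = Callable[[Genome], Fitness]


@dataclass
class Individual:
    genome: Genome
    fitness: Fitness | None = None
    rank: int | None = None
    crowding: float | None = None


@dataclass(frozen=True)
class OptimizerConfig:
    """Run settings; defaults follow common practice for integer genomes:
    crossover always applied, expected one mutated position per genome,
    binary tournaments."""

    genome_length: int
    n_objectives: int
    population_size: int = 100
    generations: int = 100
    tournament_size: int = 2
    crossover_prob: float = 1.0
    mutation_rate: float | None = None  # None -> 1 / genome_length
    n_symbols: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0.0 <= self.crossover_prob <= 1.0):
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.mutation_rate is not None and not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")

    @property
    def effective_mutation_rate(self) -> float:
        return self.mutation_rate if self.mutation_rate is not None else 1.0 / self.genome_length


@dataclass
class NSGAResult:
    population: list[Individual]
    nondominated: list[Individual]
    n_evaluations: int
    history: list[dict]

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def dominates(f1: Sequence[float], f2: Sequence[float]) -> bool:
    """Pareto dominance (minimization): f1 no worse everywhere, strictly
    better somewhere."""
    if len(f1) != len(f2):
        raise ValueError(f"fitness length mismatch: {len(f1)} vs {len(f2)}")
    strict = False
    for a, b in zip(f1, f2):
        if a > b:
            return False
        if a < b:
            strict = True
    return strict


def fast_nondominated_sort(fitnesses: Sequence[Fitness]) -> list[list[int]]:
    """Deb's fast non-dominated sort; returns fronts as lists of indices.

    Front 0 is the non-dominated set; front r is non-dominated once fronts
    < r are removed. Every index appears in exactly one front.
    """
    n = len(fitnesses)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(fitnesses[i], fitnesses[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(fitnesses[j], fitnesses[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    for i in range(n):
        if domination_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        k += 1
        fronts.append(nxt)
    fronts.pop()
    return fronts


def crowding_distance(fitnesses: Sequence[Fitness]) -> list[float]:
    """Per-individual crowding distance within one front.

    Boundary individuals on each objective get +inf; interior ones
    accumulate the range-normalized gap between their neighbours, per
    objective. Objectives with zero range contribute nothing.
    """
    n = len(fitnesses)
    if n == 0:
        return []
    n_obj = len(fitnesses[0])
    dist = [0.0] * n
    for m in range(n_obj):
        order = sorted(range(n), key=lambda i: fitnesses[i][m])
        lo = fitnesses[order[0]][m]
        hi = fitnesses[order[-1]][m]
        dist[order[0]] = math.inf
        dist[order[-1]] = math.inf
        span = hi - lo
        if span == 0:
            continue
        for pos in range(1, n - 1):
            i = order[pos]
            if dist[i] != math.inf:
                gap = fitnesses[order[pos + 1]][m] - fitnesses[order[pos - 1]][m]
                dist[i] += gap / span
    return dist


def crowded_compare(a: Individual, b: Individual) -> Individual:
    """Crowded-comparison: lower rank wins; at equal rank, larger crowding
    wins; on a full tie the first argument wins (stable)."""
    for ind in (a, b):
        if ind.rank is None or ind.crowding is None:
            raise ValueError("crowded_compare needs rank and crowding set")
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a


def hux_crossover(g1: Genome, g2: Genome, rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Half-uniform crossover: swap exactly half (floor) of the differing
    positions, chosen uniformly without replacement."""
    if len(g1) != len(g2):
        raise ValueError("genomes must have equal length")
    diff = [i for i, (a, b) in enumerate(zip(g1, g2)) if a != b]
    o1, o2 = list(g1), list(g2)
    n_swap = len(diff) // 2
    if n_swap:
        chosen = rng.choice(len(diff), size=n_swap, replace=False)
        for c in chosen:
            i = diff[c]
            o1[i], o2[i] = o2[i], o1[i]
    return tuple(o1), tuple(o2)


def flip_mutation(g: Genome, rate: float, rng: np.random.Generator,
                  n_symbols: int = 3) -> Genome:
    """Per-position flip: with probability ``rate`` replace the symbol with
    one drawn uniformly from the other symbols of the alphabet."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    out = list(g)
    for i in range(len(out)):
        if rng.random() < rate:
            shift = int(rng.integers(1, n_symbols))
            out[i] = (out[i] + shift) % n_symbols
    return tuple(out)


def _assign_rank_crowding(pool: list[Individual]) -> list[list[int]]:
    fits = [ind.fitness for ind in pool]
    fronts = fast_nondominated_sort(fits)
    for r, front in enumerate(fronts):
        dists = crowding_distance([fits[i] for i in front])
        for i, d in zip(front, dists):
            pool[i].rank = r
            pool[i].crowding = d
    return fronts


def _nondominated_merge(archive: list[Individual], fresh: list[Individual]) -> list[Individual]:
    """Non-dominated subset of archive + fresh, deduplicated by genome
    (first occurrence kept, so the archive is stable across generations)."""
    seen: set[Genome] = set()
    pool: list[Individual] = []
    for ind in archive + fresh:
        if ind.genome not in seen:
            seen.add(ind.genome)
            pool.append(ind)
    fits = [ind.fitness for ind in pool]
    keep: list[Individual] = []
    for i, ind in enumerate(pool):
        if not any(dominates(fits[j], fits[i]) for j in range(len(pool)) if j != i):
            # equal-fitness duplicates are mutually non-dominating; keep all
            keep.append(ind)
    return keep


def run(evaluator: Evaluator, config: OptimizerConfig) -> NSGAResult:
    """Generational NSGA-II loop.

    Each generation: merge current population with the elite archive, sort
    into fronts, refill the parent pool front-by-front to exactly Q
    (truncating the last admitted front by descending crowding, stable),
    then binary tournaments + HUX + flip mutation produce Q offspring which
    are evaluated and become the next population. Halts after
    ``config.generations`` generations; deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    q = config.population_size
    d = config.genome_length
    rate = config.effective_mutation_rate

    def evaluate(ind: Individual, generation: int) -> None:
        try:
            fit = tuple(float(x) for x in evaluator(ind.genome))
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed at generation {generation} on genome {ind.genome}"
            ) from exc
        if len(fit) != config.n_objectives:
            raise RuntimeError(
                f"evaluator returned {len(fit)} objectives, expected {config.n_objectives}"
            )
        ind.fitness = fit

    population = [
        Individual(tuple(int(s) for s in rng.integers(0, config.n_symbols, size=d)))
        for _ in range(q)
    ]
    for ind in population:
        evaluate(ind, 1)
    n_evaluations = q
    archive = _nondominated_merge([], population)
    history: list[dict] = []

    def record(gen: int) -> None:
        fits = np.array([ind.fitness for ind in population], dtype=float)
        entry: dict = {"generation": gen, "front_size": len(archive),
                       "n_evaluations": n_evaluations}
        for m in range(config.n_objectives):
            entry[f"best_f{m}"] = float(fits[:, m].min())
            entry[f"mean_f{m}"] = float(fits[:, m].mean())
        history.append(entry)

    record(1)

    for gen in range(2, config.generations + 1):
        merged = population + archive
        fronts = _assign_rank_crowding(merged)
        parents: list[Individual] = []
        for front in fronts:
            members = [merged[i] for i in front]
            if len(parents) + len(members) <= q:
                parents.extend(members)
            else:
                need = q - len(parents)
                # stable sort keeps insertion order at equal crowding
                members = sorted(members, key=lambda ind: -ind.crowding)
                parents.extend(members[:need])
            if len(parents) == q:
                break

        def tournament() -> Individual:
            picks = rng.integers(0, len(parents), size=config.tournament_size)
            winner = parents[picks[0]]
            for idx in picks[1:]:
                winner = crowded_compare(winner, parents[idx])
            return winner

        offspring: list[Individual] = []
        while len(offspring) < q:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_prob:
                c1, c2 = hux_crossover(p1.genome, p2.genome, rng)
            else:
                c1, c2 = p1.genome, p2.genome
            c1 = flip_mutation(c1, rate, rng, config.n_symbols)
            c2 = flip_mutation(c2, rate, rng, config.n_symbols)
            offspring.append(Individual(c1))
            if len(offspring) < q:
                offspring.append(Individual(c2))
        for ind in offspring:
            evaluate(ind, gen)
        n_evaluations += q
        population = offspring
        archive = _nondominated_merge(archive, population)
        record(gen)

    _assign_rank_crowding(population)
    return NSGAResult(
        population=population,
        nondominated=archive,
        n_evaluations=n_evaluations,
        history=history,
    )
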