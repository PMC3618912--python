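"""Genetic search for attribute reducts with rough-set dependency fitness.

A chromosome is an ordered list of k distinct condition-attribute indices;
its fitness is the dependency degree γ of that subset on the decision.
Candidates with γ at or above a user threshold α are accepted as reducts.
Breeding pools are built from the union of the last two generations,
ranked by fitness.  Three selection strategies are supported:

* ``roulette`` — fitness-proportionate sampling;
* ``artificial_classical`` — fixed percentages of best- and worst-ranked
  chromosomes;
* ``artificial_modified`` — best, worst, *and* a middle region starting at
  the median rank and extending toward worse ranks.  Seeding the first two
  generations randomly (with duplicate suppression) plus the middle region
  keeps diversity up and avoids stalling on local optima.

Recombination is linear order crossover (LOX): equal-length sublists cut
at independent positions are exchanged and the holes refilled with the
recipient's remaining genes in their original relative order, so children
never repeat a gene.  Mutation swaps two or three gene positions for
attributes currently outside the chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np

from .decision_table import DecisionTable
from . import rough_core

__all__ = [
    "Chromosome",
    "GenePool",
    "SelectionConfig",
    "GAConfig",
    "GAResult",
    "AcceptedReduct",
    "init_population",
    "roulette_select",
    "artificial_select",
    "lox_crossover",
    "mutate",
    "run_search",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chromosome:
    """Ordered distinct attribute indices; order matters for crossover."""

    genes: tuple[int, ...]
    fitness: Fraction | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome genes must be distinct")
        if not self.genes:
            raise ValueError("chromosome must have at least one gene")

    @property
    def gene_set(self) -> frozenset[int]:
        return frozenset(self.genes)

    def evaluated(self) -> "Chromosome":
        if self.fitness is None:
            raise ValueError("fitness not evaluated")
        return self


@dataclass(frozen=True)
class GenePool:
    """Last two generations, deduplicated by gene set, fitness-descending."""

    members: tuple[Chromosome, ...]

    @classmethod
    def from_generations(cls, *generations: Sequence[Chromosome]) -> "GenePool":
        seen: dict[frozenset[int], Chromosome] = {}
        for gen in generations:
            for ch in gen:
                ch.evaluated()
                key = ch.gene_set
                if key not in seen:
                    seen[key] = ch
        members = sorted(seen.values(), key=lambda c: (-c.fitness, sorted(c.genes)))
        return cls(tuple(members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SelectionConfig:
    strategy: str = "artificial_modified"  # roulette | artificial_classical | artificial_modified
    best_pct: float = 33.0
    mid_pct: float = 34.0
    worst_pct: float = 33.0

    def __post_init__(self) -> None:
        if self.strategy not in ("roulette", "artificial_classical", "artificial_modified"):
            raise ValueError(f"unknown selection strategy {self.strategy!r}")
        if min(self.best_pct, self.mid_pct, self.worst_pct) < 0:
            raise ValueError("selection percentages must be non-negative")
        if self.strategy == "artificial_modified":
            if self.best_pct + self.mid_pct + self.worst_pct != 100:
                raise ValueError("modified selection requires best% + mid% + worst% = 100")
        elif self.strategy == "artificial_classical":
            if self.best_pct + self.worst_pct != 100:
                raise ValueError("classical selection requires best% + worst% = 100")
            if self.mid_pct != 0:
                raise ValueError("classical selection takes no middle region")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    crossover_rate: float = 0.5
    mutation_rate: float = 0.5
    mutation_kind: str = "mixed"  # swap2 | swap3 | mixed
    alpha: float = 0.96
    max_generations: int = 100
    subset_size_range: tuple[int, int] = (5, 7)
    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    stop_on_first: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.mutation_kind not in ("swap2", "swap3", "mixed"):
            raise ValueError(f"unknown mutation kind {self.mutation_kind!r}")
        kmin, kmax = self.subset_size_range
        if kmin < 1 or kmin > kmax:
            raise ValueError("invalid subset size range")


@dataclass(frozen=True)
class AcceptedReduct:
    attrs: frozenset[int]
    gamma: Fraction
    minimal: bool


@dataclass(frozen=True)
class GAResult:
    accepted: tuple[AcceptedReduct, ...]
    generations_run: int
    first_acceptance_generation: int | None
    strategy: str
    seed: int


class _Evaluator:
    """Memoizing γ evaluator over one table."""

    def __init__(self, table: DecisionTable):
        self.table = table
        self._cache: dict[frozenset[int], Fraction] = {}

    def __call__(self, ch: Chromosome) -> Chromosome:
        if ch.fitness is not None:
            return ch
        key = ch.gene_set
        if key not in self._cache:
            self._cache[key] = rough_core.dependency(self.table, key).gamma
        return replace(ch, fitness=self._cache[key])


def _random_chromosome(n_attrs: int, k: int, rng: np.random.Generator) -> Chromosome:
    genes = tuple(int(g) for g in rng.choice(n_attrs, size=k, replace=False))
    return Chromosome(genes)


def init_population(
    table: DecisionTable, config: GAConfig, k: int, rng: np.random.Generator
) -> tuple[list[Chromosome], list[Chromosome]]:
    """Two random starting generations with cross-generation duplicate suppression.

    A candidate whose gene set already occurs in either generation is
    redrawn (bounded retries; with tiny search spaces duplicates are
    eventually tolerated rather than looping forever).
    """
    if k > table.n_attrs:
        raise ValueError(f"subset size {k} exceeds attribute count {table.n_attrs}")
    evaluate = _Evaluator(table)
    seen: set[frozenset[int]] = set()
    generations: list[list[Chromosome]] = []
    for _ in range(2):
        gen: list[Chromosome] = []
        for _ in range(config.population_size):
            ch = _random_chromosome(table.n_attrs, k, rng)
            for _ in range(50):
                if ch.gene_set not in seen:
                    break
                ch = _random_chromosome(table.n_attrs, k, rng)
            seen.add(ch.gene_set)
            gen.append(evaluate(ch))
        generations.append(gen)
    return generations[0], generations[1]


def roulette_select(pool: GenePool, n: int, rng: np.random.Generator) -> list[Chromosome]:
    """n independent fitness-proportionate draws (uniform if all fitness is 0)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not len(pool):
        raise ValueError("empty pool")
    fit = np.array([float(c.fitness) for c in pool.members])
    total = fit.sum()
    probs = fit / total if total > 0 else np.full(len(fit), 1.0 / len(fit))
    picks = rng.choice(len(pool), size=n, replace=True, p=probs)
    return [pool.members[i] for i in picks]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def artificial_select(
    pool: GenePool,
    config: SelectionConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[Chromosome]:
    """Rank-region selection of an intermediate generation of size ``n``.

    Classical: best and worst percentage regions only.  Modified: a third,
    middle region whose picks start at the rank just past the median of
    the descending-sorted pool and proceed toward worse ranks,
    skipping ranks already taken by the other regions.  Region sizes use
    round-half-up with the remainder assigned to the middle (classical:
    worst) region so they always sum to ``n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    size = len(pool)
    if size == 0:
        raise ValueError("empty pool")

    n_best = _round_half_up(config.best_pct / 100.0 * n)
    if config.strategy == "artificial_classical":
        n_best = min(n_best, n)
        n_worst, n_mid = n - n_best, 0
    elif config.strategy == "artificial_modified":
        n_worst = _round_half_up(config.worst_pct / 100.0 * n)
        if n_best + n_worst > n:  # rounding overshoot on tiny n
            n_worst = max(0, n - n_best)
            n_best = min(n_best, n)
        n_mid = n - n_best - n_worst
    else:
        raise ValueError("artificial_select requires an artificial strategy")

    chosen: list[int] = []
    taken: set[int] = set()

    def take(rank_order: Sequence[int], count: int) -> None:
        for r in rank_order:
            if count == 0:
                return
            if r not in taken:
                taken.add(r)
                chosen.append(r)
                count -= 1

    take(range(size), n_best)
    take(range(size - 1, -1, -1), n_worst)
    if n_mid:
        mid_start = size // 2  # 0-based: rank ceil(size/2)+... median point, next rank down
        order = list(range(mid_start, size)) + list(range(mid_start - 1, -1, -1))
        take(order, n_mid)

    selected = [pool.members[r] for r in chosen]
    if len(selected) < n:
        # Pool smaller than the target generation: refill from the worst
        # region with replacement.
        deficit = n - len(selected)
        logger.warning("pool of %d smaller than target %d; re-sampling worst region", size, n)
        if rng is None:
            raise ValueError("rng required to refill from an undersized pool")
        tail_lo = max(0, size - max(1, _round_half_up(getattr(config, "worst_pct", 50) / 100.0 * size)))
        picks = rng.integers(tail_lo, size, size=deficit)
        selected.extend(pool.members[int(i)] for i in picks)
    return selected


def lox_crossover(
    p1: Chromosome, p2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Linear order crossover on equal-length parents.

    A sublist length is drawn once; each parent contributes a sublist cut
    at its own independently drawn start.  Each child keeps its recipient
    parent's frame: the donor sublist lands at the recipient's cut
    position and the remaining slots are filled left-to-right with the
    recipient's genes not present in the donor sublist, preserving their
    original order.
    """
    k = len(p1.genes)
    if len(p2.genes) != k:
        raise ValueError("LOX requires equal-length parents")
    length = int(rng.integers(0, k + 1))
    if length == 0:
        return replace(p1, fitness=None), replace(p2, fitness=None)
    s1 = int(rng.integers(0, k - length + 1))
    s2 = int(rng.integers(0, k - length + 1))

    def make_child(recipient: Chromosome, donor_slice: tuple[int, ...], cut: int) -> Chromosome:
        filler = [g for g in recipient.genes if g not in donor_slice]
        child: list[int] = []
        fi = 0
        for pos in range(k):
            if cut <= pos < cut + length:
                child.append(donor_slice[pos - cut])
            else:
                child.append(filler[fi])
                fi += 1
        return Chromosome(tuple(child))

    c1 = make_child(p1, p2.genes[s2 : s2 + length], s1)
    c2 = make_child(p2, p1.genes[s1 : s1 + length], s2)
    return c1, c2


def mutate(
    ch: Chromosome, kind: str, n_attrs: int, rng: np.random.Generator
) -> Chromosome:
    """Swap 2 or 3 gene positions for attributes outside the chromosome.

    When fewer outside attributes exist than the operator's arity, the
    chosen positions are permuted in place instead, so gene distinctness
    is always preserved.  Fitness is invalidated.
    """
    arity = {"swap2": 2, "swap3": 3}[kind]
    k = len(ch.genes)
    if k < arity:
        raise ValueError(f"{kind} needs at least {arity} genes, chromosome has {k}")
    genes = list(ch.genes)
    positions = [int(p) for p in rng.choice(k, size=arity, replace=False)]
    outside = [a for a in range(n_attrs) if a not in ch.gene_set]
    if len(outside) >= arity:
        replacements = [outside[int(i)] for i in rng.choice(len(outside), size=arity, replace=False)]
        for pos, new in zip(positions, replacements):
            genes[pos] = new
    else:
        perm = [int(i) for i in rng.permutation(arity)]
        old = [genes[p] for p in positions]
        for pos, src in zip(positions, perm):
            genes[pos] = old[src]
    return Chromosome(tuple(genes))


def _pick_mutation_kind(config: GAConfig, k: int, rng: np.random.Generator) -> str:
    if config.mutation_kind != "mixed":
        return config.mutation_kind
    if k < 3:
        return "swap2"
    return "swap2" if rng.random() < 0.5 else "swap3"


def run_search(table: DecisionTable, config: GAConfig) -> GAResult:
    """Full reduct search: one GA run per subset size k in the configured range.

    Every evaluated chromosome with γ ≥ α is accumulated; by default the
    loop runs out its generation budget to collect many reducts, while
    ``stop_on_first`` stops a size's run at the first acceptance.  The
    result is reproducible from (table, config): a single seeded generator
    drives every stochastic step.
    """
    rng = np.random.default_rng(config.seed)
    evaluate = _Evaluator(table)
    alpha = Fraction(config.alpha).limit_denominator(10**9)
    accepted: dict[frozenset[int], Fraction] = {}
    generations_run = 0
    first_acceptance: int | None = None

    def record(chromosomes: Sequence[Chromosome], generation_idx: int) -> None:
        nonlocal first_acceptance
        for ch in chromosomes:
            if ch.fitness >= alpha and ch.gene_set not in accepted:
                accepted[ch.gene_set] = ch.fitness
                if first_acceptance is None:
                    first_acceptance = generation_idx

    kmin, kmax = config.subset_size_range
    kmax = min(kmax, table.n_attrs)
    for k in range(kmin, kmax + 1):
        gen_a, gen_b = init_population(table, config, k, rng)
        record(gen_a, 1)
        record(gen_b, 2)
        generations_run += 2
        for gen_idx in range(3, config.max_generations + 1):
            if config.stop_on_first and accepted:
                break
            pool = GenePool.from_generations(gen_a, gen_b)
            if config.selection.strategy == "roulette":
                intermediate = roulette_select(pool, config.population_size, rng)
            else:
                intermediate = artificial_select(
                    pool, config.selection, config.population_size, rng=rng
                )
            offspring: list[Chromosome] = []
            for i in range(0, len(intermediate) - 1, 2):
                p1, p2 = intermediate[i], intermediate[i + 1]
                if len(p1.genes) == len(p2.genes) and rng.random() < config.crossover_rate:
                    c1, c2 = lox_crossover(p1, p2, rng)
                else:
                    c1, c2 = replace(p1, fitness=None), replace(p2, fitness=None)
                offspring.extend((c1, c2))
            mutated: list[Chromosome] = []
            for ch in offspring:
                if rng.random() < config.mutation_rate:
                    kind = _pick_mutation_kind(config, len(ch.genes), rng)
                    ch = mutate(ch, kind, table.n_attrs, rng)
                mutated.append(evaluate(ch))
            record(mutated, gen_idx)
            generations_run += 1
            gen_a, gen_b = gen_b, mutated
            logger.debug("k=%d generation %d best γ=%s", k, gen_idx, max(c.fitness for c in mutated))

    results = []
    for attrs in sorted(accepted, key=lambda s: (len(s), sorted(s))):
        g = rough_core.dependency(table, attrs).gamma  # post-hoc recheck, no stale fitness
        assert g == accepted[attrs]
        results.append(
            AcceptedReduct(attrs, g, rough_core.is_minimal_reduct(table, attrs, config.alpha))
        )
    return GAResult(
        tuple(results), generations_run, first_acceptance, config.selection.strategy, config.seed
    )
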