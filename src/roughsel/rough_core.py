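"""Rough-set machinery: indiscernibility, approximations, dependency.

Two objects are indiscernible with respect to an attribute subset ``P``
when they agree on every attribute of ``P``; the equivalence classes of
that relation partition the universe.  A target set ``X`` is approximated
from below by the union of classes fully contained in it and from above by
the union of classes meeting it.  The positive region ``POS_P(D)`` is the
union of lower approximations of the decision classes, and the dependency
degree ``γ_P(D) = |POS_P(D)| / |U|`` measures how completely ``P``
determines the decision.  ``γ`` is the fitness driving the genetic reduct
search and the acceptance test for candidate reducts (γ ≥ α).

All counts use exact integer arithmetic; γ is exposed both as a
``Fraction`` and a float so threshold comparisons (e.g. α = 0.96) never
hinge on floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import FrozenSet, Iterable, Sequence

import numpy as np

from .decision_table import DecisionTable

__all__ = [
    "Partition",
    "RegionReport",
    "DependencyResult",
    "equivalence_classes",
    "approximate",
    "positive_region",
    "dependency",
    "exhaustive_reduct_search",
    "is_minimal_reduct",
]


@dataclass(frozen=True)
class Partition:
    """Indiscernibility partition of the universe induced by an attribute subset."""

    blocks: tuple[frozenset[int], ...]
    generated_by: frozenset[int]

    def block_of(self, obj: int) -> frozenset[int]:
        for b in self.blocks:
            if obj in b:
                return b
        raise KeyError(f"object {obj} not in any block")


@dataclass(frozen=True)
class RegionReport:
    """Lower/upper approximations and the derived regions for one target set."""

    lower: frozenset[int]
    upper: frozenset[int]
    boundary: frozenset[int]
    positive: frozenset[int]
    negative: frozenset[int]


@dataclass(frozen=True)
class DependencyResult:
    """Dependency degree γ_P(D) with its exact positive-region count."""

    gamma: Fraction
    positive_count: int
    universe_count: int
    subset: frozenset[int]

    @property
    def gamma_float(self) -> float:
        return float(self.gamma)

    def sort_key(self) -> tuple:
        return (len(self.subset), -self.gamma, tuple(sorted(self.subset)))


def _check_subset(table: DecisionTable, subset: Iterable[int]) -> tuple[int, ...]:
    cols = tuple(int(a) for a in subset)
    for a in cols:
        if not 0 <= a < table.n_attrs:
            raise IndexError(f"attribute index {a} out of range [0, {table.n_attrs})")
    return cols

def _block_labels(table: DecisionTable, cols: Sequence[int]) -> np.ndarray:
    """Per-object block id under the indiscernibility relation of ``cols``."""
    n = table.n_objects
    if not cols:
        return np.zeros(n, dtype=np.int64)
    _, inverse = np.unique(table.rows[:, list(cols)], axis=0, return_inverse=True)
    return inverse


def equivalence_classes(table: DecisionTable, subset: Iterable[int]) -> Partition:
    """Partition objects into classes agreeing on every attribute of ``subset``.

    The empty subset induces the trivial one-block partition.
    """
    cols = _check_subset(table, subset)
    labels = _block_labels(table, cols)
    blocks = [frozenset(np.flatnonzero(labels == b).tolist()) for b in range(labels.max() + 1)]
    return Partition(tuple(blocks), frozenset(cols))


def approximate(table: DecisionTable, subset: Iterable[int], target: Iterable[int]) -> RegionReport:
    """Lower/upper approximation of the object set ``target`` under ``subset``."""
    x = frozenset(int(i) for i in target)
    for i in x:
        if not 0 <= i < table.n_objects:
            raise IndexError(f"object index {i} out of range")
    part = equivalence_classes(table, subset)
    lower: set[int] = set()
    upper: set[int] = set()
    for block in part.blocks:
        if block <= x:
            lower |= block
        if block & x:
            upper |= block
    universe = frozenset(range(table.n_objects))
    lo, up = frozenset(lower), frozenset(upper)
    return RegionReport(lo, up, up - lo, lo, universe - up)


def positive_region(table: DecisionTable, subset: Iterable[int]) -> frozenset[int]:
    """POS_P(D): union of lower approximations of the decision classes.

    Equivalently, the union of P-blocks whose objects all share one
    decision value.
    """
    cols = _check_subset(table, subset)
    labels = _block_labels(table, cols)
    pos: set[int] = set()
    for b in range(labels.max() + 1):
        members = np.flatnonzero(labels == b)
        if np.unique(table.decisions[members]).size == 1:
            pos.update(members.tolist())
    return frozenset(pos)


def dependency(table: DecisionTable, subset: Iterable[int]) -> DependencyResult:
    """Dependency degree γ_P(D) = |POS_P(D)| / |U| of ``subset`` on the decision."""
    if table.n_objects == 0:
        raise ValueError("dependency is undefined on an empty table")
    cols = _check_subset(table, subset)
    pos = len(positive_region(table, cols))
    return DependencyResult(Fraction(pos, table.n_objects), pos, table.n_objects, frozenset(cols))


def gamma(table: DecisionTable, subset: Iterable[int]) -> float:
    """Convenience: γ_P(D) as a float."""
    return dependency(table, subset).gamma_float


def exhaustive_reduct_search(
    table: DecisionTable,
    size_range: tuple[int, int],
    alpha: float = 1.0,
    max_attrs: int = 20,
) -> list[DependencyResult]:
    """Enumerate every attribute subset in the size range; keep those with γ ≥ alpha.

    This is the brute-force comparator used as the correctness oracle for
    the genetic and discernibility-based reducers.  It refuses tables wider
    than ``max_attrs`` (combinatorial guard).  Results are sorted by
    (size, -γ, attribute indices) for deterministic output.
    """
    kmin, kmax = size_range
    if kmin < 1 or kmax > table.n_attrs or kmin > kmax:
        raise ValueError(f"size range [{kmin}, {kmax}] invalid for {table.n_attrs} attributes")
    if table.n_attrs > max_attrs:
        raise ValueError(
            f"exhaustive search refused: {table.n_attrs} attributes exceeds cap {max_attrs}"
        )
    alpha_frac = Fraction(alpha).limit_denominator(10**9)
    out = []
    for k in range(kmin, kmax + 1):
        for combo in combinations(range(table.n_attrs), k):
            res = dependency(table, combo)
            if res.gamma >= alpha_frac:
                out.append(res)
    out.sort(key=DependencyResult.sort_key)
    return out


def is_minimal_reduct(table: DecisionTable, subset: Iterable[int], alpha: float = 1.0) -> bool:
    """True iff γ(subset) ≥ alpha and dropping any single attribute breaks that."""
    cols = _check_subset(table, subset)
    if not cols:
        raise ValueError("subset must be nonempty")
    alpha_frac = Fraction(alpha).limit_denominator(10**9)
    if dependency(table, cols).gamma < alpha_frac:
        return False
    return all(
        dependency(table, [a for a in cols if a != drop]).gamma < alpha_frac for drop in cols
    )


def minimal_reducts(table: DecisionTable, alpha: float = 1.0, max_attrs: int = 20) -> set[FrozenSet[int]]:
    """All minimal attribute subsets with γ ≥ alpha, by direct enumeration.

    Independent oracle for the prime-implicant reducer: enumerates subsets
    in increasing size and keeps those containing no smaller kept subset.
    """
    if table.n_attrs > max_attrs:
        raise ValueError("minimal_reducts refused: attribute count exceeds cap")
    alpha_frac = Fraction(alpha).limit_denominator(10**9)
    found: set[FrozenSet[int]] = set()
    for k in range(1, table.n_attrs + 1):
        for combo in combinations(range(table.n_attrs), k):
            s = frozenset(combo)
            if any(r <= s for r in found):
                continue
            if dependency(table, combo).gamma >= alpha_frac:
                found.add(s)
    return found


def format_report(results: Sequence[DependencyResult], attr_names: Sequence[str]) -> str:
    """Tab-separated reduct report: element number, attribute list, γ."""
    lines = ["element_number\treduct\tdependency"]
    for res in results:
        attrs = "".join(attr_names[a] for a in sorted(res.subset))
        g = res.gamma
        gtxt = "1" if g == 1 else f"{float(g):.3f}"
        lines.append(f"{len(res.subset)}\t{attrs}\t{gtxt}")
    return "\n".join(lines)
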