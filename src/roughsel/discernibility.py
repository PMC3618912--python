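"""Decision-relative discernibility matrix, CNF function, and reducers.

For every pair of objects with different decision values the discernibility
matrix records the set of condition attributes on which the pair differs.
The discernibility function is the conjunction (over non-empty cells) of
the disjunctions of each cell's attributes; after absorption its prime
implicants are exactly the decision-relative reducts.  Two reducers are
provided: exact prime-implicant enumeration by clause distribution with
absorption pruning (exponential in the worst case, hence resource-capped),
and the Johnson greedy weighted-cover heuristic, which returns a single
approximate reduct quickly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Mapping, Sequence

import numpy as np

from .decision_table import DecisionTable

__all__ = [
    "DiscernibilityMatrix",
    "BooleanCNF",
    "ImplicantSet",
    "build_matrix",
    "discernibility_function",
    "prime_implicants",
    "johnson_reduce",
]

AttrSet = FrozenSet[int]


@dataclass(frozen=True)
class DiscernibilityMatrix:
    """Cells keyed by unordered object pair (i < j), different decisions only."""

    cells: Mapping[tuple[int, int], AttrSet]
    universe_size: int

    def nonempty_cells(self) -> list[AttrSet]:
        return [c for c in self.cells.values() if c]

    def inconsistent_pairs(self) -> list[tuple[int, int]]:
        """Pairs indiscernible on all attributes yet decided differently."""
        return sorted(pair for pair, cell in self.cells.items() if not cell)


@dataclass(frozen=True)
class BooleanCNF:
    """Conjunction of attribute disjunctions, absorption-normalized."""

    clauses: frozenset[AttrSet]

    def variables(self) -> AttrSet:
        out: set[int] = set()
        for c in self.clauses:
            out |= c
        return frozenset(out)


@dataclass(frozen=True)
class ImplicantSet:
    """DNF terms (each a conjunction); ``complete`` is False if capped."""

    implicants: frozenset[AttrSet]
    complete: bool


def build_matrix(table: DecisionTable) -> DiscernibilityMatrix:
    """Discernibility cells for every cross-decision object pair."""
    if table.n_objects == 0:
        raise ValueError("table is empty")
    cells: dict[tuple[int, int], AttrSet] = {}
    rows, dec = table.rows, table.decisions
    for i in range(table.n_objects):
        for j in range(i + 1, table.n_objects):
            if dec[i] == dec[j]:
                continue
            diff = np.flatnonzero(rows[i] != rows[j])
            cells[(i, j)] = frozenset(diff.tolist())
    return DiscernibilityMatrix(cells, table.n_objects)


def absorb(clauses: Iterable[AttrSet]) -> frozenset[AttrSet]:
    """Drop any clause that is a superset of another (absorption law)."""
    unique = sorted(set(clauses), key=lambda c: (len(c), sorted(c)))
    kept: list[AttrSet] = []
    for c in unique:
        if not any(k <= c for k in kept):
            kept.append(c)
    return frozenset(kept)


def discernibility_function(matrix: DiscernibilityMatrix) -> BooleanCNF:
    """CNF over the non-empty matrix cells, deduplicated and absorbed.

    Empty cells mark inconsistent pairs and are excluded; if *all* cells
    are empty (or none exist) the decision is independent of the
    attributes and no function can be built.
    """
    clauses = matrix.nonempty_cells()
    if not clauses:
        raise ValueError("no non-empty discernibility cells; decision independent of attributes")
    return BooleanCNF(absorb(clauses))


def prime_implicants(cnf: BooleanCNF, max_terms: int = 200_000) -> ImplicantSet:
    """CNF → DNF by iterative clause distribution with absorption pruning.

    When the run completes, the implicants are exactly the minimal hitting
    sets of the clause family, i.e. all decision-relative reducts.  If the
    intermediate term count would exceed ``max_terms`` the expansion stops
    and the partial result is flagged ``complete=False``.
    """
    if not cnf.clauses:
        raise ValueError("empty CNF")
    # Distribute smaller clauses first: keeps intermediate DNFs tight.
    ordered = sorted(cnf.clauses, key=lambda c: (len(c), sorted(c)))
    terms: set[AttrSet] = {frozenset()}
    for clause in ordered:
        new_terms: set[AttrSet] = set()
        for t in terms:
            if t & clause:  # already hits this clause
                new_terms.add(t)
                continue
            for a in clause:
                new_terms.add(t | {a})
        terms = set(absorb(new_terms))
        if len(terms) > max_terms:
            return ImplicantSet(frozenset(terms), complete=False)
    return ImplicantSet(frozenset(terms), complete=True)


def johnson_reduce(
    cnf: BooleanCNF,
    weights: Sequence[float] | None = None,
    abort_fraction: float | None = None,
) -> frozenset[int]:
    """Greedy weighted set cover over the discernibility clauses.

    Repeatedly picks the attribute maximizing the summed weight of the
    still-uncovered clauses containing it (ties broken toward the lowest
    attribute index), removes the clauses it covers, and stops when all
    clauses are covered — or earlier, once the covered weight fraction
    reaches ``abort_fraction`` (approximate mode).  Default weights are 1
    per clause.
    """
    clauses = sorted(cnf.clauses, key=lambda c: (len(c), sorted(c)))
    if not clauses:
        raise ValueError("empty CNF")
    if weights is None:
        w = [1.0] * len(clauses)
    else:
        if len(weights) != len(clauses):
            raise ValueError(f"expected {len(clauses)} clause weights, got {len(weights)}")
        w = [float(x) for x in weights]
    total = sum(w)
    covered = 0.0
    remaining = list(range(len(clauses)))
    chosen: set[int] = set()
    while remaining:
        if abort_fraction is not None and total > 0 and covered / total >= abort_fraction:
            break
        score: dict[int, float] = {}
        for idx in remaining:
            for a in clauses[idx]:
                score[a] = score.get(a, 0.0) + w[idx]
        best = min(score, key=lambda a: (-score[a], a))
        chosen.add(best)
        newly = [idx for idx in remaining if best in clauses[idx]]
        covered += sum(w[idx] for idx in newly)
        remaining = [idx for idx in remaining if best not in clauses[idx]]
    return frozenset(chosen)


def format_function(cnf: BooleanCNF, attr_names: Sequence[str]) -> str:
    """Render the CNF in `(a1+a2)*(a3+a4)` notation (+ union, * intersection)."""
    parts = []
    for clause in sorted(cnf.clauses, key=lambda c: (len(c), sorted(c))):
        parts.append("(" + "+".join(attr_names[a] for a in sorted(clause)) + ")")
    return "*".join(parts)


def format_implicants(imps: ImplicantSet, attr_names: Sequence[str]) -> str:
    """Render DNF terms like `a1a2a3a8a10`, joined by `+`."""
    terms = sorted(imps.implicants, key=lambda t: (len(t), sorted(t)))
    return "+".join("".join(attr_names[a] for a in sorted(t)) for t in terms)
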