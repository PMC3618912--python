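"""Discrete decision tables for uroflowmetry-based risk classification.

A decision table is the rough-set data model ``(U, C ∪ D)``: a universe of
objects (one row per patient), a set of integer-coded condition attributes
``C`` (here ``a1..a12``: maximum flow rate, average flow rate, residual
urine volume, and nine flow-rate samples taken between T/4 and 3T/4 of the
voiding time T), and a single decision attribute ``d`` coding the clinical
risk group (1 = very risky, 2 = risky, 3 = healthy).

This module provides the in-memory container, CSV round-trip I/O, the
crisp linguistic discretization of raw uroflowmetric measurements, a
bundled 15-patient sample table, and a seeded synthetic generator used
throughout the test harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionTable",
    "LinguisticScheme",
    "RawUroflowRecord",
    "SyntheticSpec",
    "MeasurementRangeError",
    "TableParseError",
    "SCHEMES",
    "encode_value",
    "discretize_record",
    "read_table",
    "write_table",
    "table1_fixture",
    "synthesize_table",
]

DEFAULT_CLASS_LABELS: Mapping[int, str] = {1: "very risky", 2: "risky", 3: "healthy"}


class MeasurementRangeError(ValueError):
    """Raw measurement outside the total range of its linguistic scheme."""


class TableParseError(ValueError):
    """Malformed decision-table file; message carries row/column position."""


@dataclass(frozen=True)
class DecisionTable:
    """Objects × integer-coded condition attributes plus one decision column.

    Parameters
    ----------
    rows
        ``(n_objects, n_attrs)`` array of positive integer codes.
    decisions
        Length ``n_objects`` vector of positive integer class codes.
    attr_names
        Ordered condition-attribute labels, ``a1..a12`` by default.
    class_labels
        Decision code → clinical group name.
    """

    rows: np.ndarray
    decisions: np.ndarray
    attr_names: tuple[str, ...] = ()
    class_labels: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_LABELS))

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.int64)
        decisions = np.asarray(self.decisions, dtype=np.int64)
        if rows.ndim != 2 or rows.shape[1] < 1:
            raise ValueError("rows must be a 2-D array with at least one attribute")
        if decisions.shape != (rows.shape[0],):
            raise ValueError("decisions length must equal the number of rows")
        if rows.size and rows.min() < 1:
            raise ValueError("attribute codes must be positive integers")
        if decisions.size and decisions.min() < 1:
            raise ValueError("decision codes must be positive integers")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "decisions", decisions)
        names = tuple(self.attr_names) or tuple(f"a{i + 1}" for i in range(rows.shape[1]))
        if len(names) != rows.shape[1]:
            raise ValueError("attr_names length must match the attribute count")
        object.__setattr__(self, "attr_names", names)

    @property
    def n_objects(self) -> int:
        return self.rows.shape[0]

    @property
    def n_attrs(self) -> int:
        return self.rows.shape[1]

    def attr_index(self, name: str) -> int:
        try:
            return self.attr_names.index(name)
        except ValueError:
            raise KeyError(f"unknown attribute {name!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecisionTable):
            return NotImplemented
        return (
            np.array_equal(self.rows, other.rows)
            and np.array_equal(self.decisions, other.decisions)
            and self.attr_names == other.attr_names
        )


@dataclass(frozen=True)
class _Bin:
    lower: float
    upper: float
    lower_inclusive: bool
    upper_inclusive: bool
    code: int
    label: str

    def contains(self, value: float) -> bool:
        lo = value >= self.lower if self.lower_inclusive else value > self.lower
        hi = value <= self.upper if self.upper_inclusive else value < self.upper
        return lo and hi


@dataclass(frozen=True)
class LinguisticScheme:
    """Ordered crisp bins mapping one measurement kind to codes 1..4."""

    kind: str
    unit: str
    bins: tuple[_Bin, ...]

    @property
    def total_lower(self) -> float:
        return self.bins[0].lower

    @property
    def total_upper(self) -> float:
        return self.bins[-1].upper

    def encode(self, value: float) -> int:
        for b in self.bins:
            if b.contains(value):
                return b.code
        raise MeasurementRangeError(
            f"{self.kind} value {value} outside [{self.total_lower}, "
            f"{self.total_upper}] {self.unit}"
        )


def _scheme(kind: str, unit: str, spec: Sequence[tuple[float, float, bool, bool, str]]) -> LinguisticScheme:
    bins = tuple(
        _Bin(lo, hi, lo_inc, hi_inc, code, label)
        for code, (lo, hi, lo_inc, hi_inc, label) in enumerate(spec, start=1)
    )
    return LinguisticScheme(kind, unit, bins)


# Flow-rate bins are half-open [lo, hi) except the final bin, which closes the
# total range.  Residual volume is special: code 1 is exactly 0 ml ("none"),
# code 2 the open interval up to 50 ml.
_AVG_FLOW_SPEC = [
    (0, 7, True, False, "Very Low"),
    (7, 14, True, False, "Low"),
    (14, 25, True, False, "Medium"),
    (25, 40, True, True, "High"),
]

SCHEMES: Mapping[str, LinguisticScheme] = {
    "max_flow": _scheme(
        "max_flow",
        "ml/s",
        [
            (0, 10, True, False, "Very Low"),
            (10, 20, True, False, "Low"),
            (20, 30, True, False, "Medium"),
            (30, 40, True, True, "High"),
        ],
    ),
    "avg_flow": _scheme("avg_flow", "ml/s", _AVG_FLOW_SPEC),
    # The nine sampled flow rates reuse the average-flow thresholds.
    "sampled_flow": _scheme("sampled_flow", "ml/s", _AVG_FLOW_SPEC),
    "residual_volume": _scheme(
        "residual_volume",
        "ml",
        [
            (0, 0, True, True, "None"),
            (0, 50, False, False, "Medium"),
            (50, 150, True, False, "High"),
            (150, 500, True, True, "Very High"),
        ],
    ),
}


def encode_value(kind: str, value: float) -> int:
    """Map one raw measurement to its linguistic code 1..4.

    Raises :class:`MeasurementRangeError` when ``value`` falls outside the
    scheme's total range (e.g. above 40 ml/s for the maximum flow rate).
    """
    if kind not in SCHEMES:
        raise KeyError(f"unknown measurement kind {kind!r}; one of {sorted(SCHEMES)}")
    return SCHEMES[kind].encode(value)


@dataclass(frozen=True)
class RawUroflowRecord:
    """One patient's raw uroflowmetric measurements before discretization."""

    max_flow: float
    avg_flow: float
    residual_volume: float
    sampled_flows: tuple[float, ...]

    def __post_init__(self) -> None:
        flows = tuple(float(v) for v in self.sampled_flows)
        if len(flows) != 9:
            raise ValueError(f"expected exactly 9 sampled flows, got {len(flows)}")
        if min((self.max_flow, self.avg_flow, self.residual_volume) + flows) < 0:
            raise ValueError("measurements must be non-negative")
        object.__setattr__(self, "sampled_flows", flows)


def discretize_record(rec: RawUroflowRecord) -> tuple[int, ...]:
    """Encode one raw record as the 12-code row (a1..a12)."""
    fields = [("max_flow", rec.max_flow), ("avg_flow", rec.avg_flow), ("residual_volume", rec.residual_volume)]
    fields += [("sampled_flow", v) for v in rec.sampled_flows]
    codes = []
    for i, (kind, value) in enumerate(fields):
        try:
            codes.append(encode_value(kind, value))
        except MeasurementRangeError as exc:
            raise MeasurementRangeError(f"field a{i + 1}: {exc}") from exc
    return tuple(codes)


def read_table(path) -> DecisionTable:
    """Read a decision table from CSV (header names attributes, ``d`` last)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{path}: empty file") from None
    if df.shape[1] < 2:
        raise TableParseError(f"{path}: need at least one attribute column and 'd'")
    if df.columns[-1] != "d":
        raise TableParseError(f"{path}: last column must be the decision column 'd', got {df.columns[-1]!r}")
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() | (series != series.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(f"{path}: non-integer cell at row {row + 1}, column {col!r}")
    values = df.to_numpy(dtype=np.int64)
    return DecisionTable(values[:, :-1], values[:, -1], tuple(df.columns[:-1]))


def write_table(table: DecisionTable, path) -> None:
    df = pd.DataFrame(table.rows, columns=list(table.attr_names))
    df["d"] = table.decisions
    df.to_csv(path, index=False)


# The 15 published sample transactions: columns a1..a12 then d.
_SAMPLE_ROWS = np.array(
    [
        [1, 1, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 3, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        [1, 1, 2, 1, 1, 1, 1, 2, 1, 1, 1, 1, 1],
        [2, 1, 1, 2, 1, 2, 1, 1, 1, 2, 1, 1, 1],
        [2, 1, 1, 1, 1, 1, 2, 1, 1, 2, 1, 2, 1],
        [2, 1, 2, 1, 2, 1, 1, 1, 1, 2, 1, 1, 1],
        [2, 1, 2, 1, 1, 1, 2, 2, 2, 1, 1, 1, 1],
        [3, 3, 1, 3, 3, 3, 4, 3, 3, 3, 3, 3, 3],
        [3, 3, 1, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3],
        [2, 1, 1, 2, 1, 2, 1, 1, 1, 2, 1, 1, 1],
        [4, 3, 1, 3, 3, 3, 4, 3, 3, 3, 3, 3, 3],
        [2, 1, 1, 2, 1, 1, 1, 2, 2, 1, 1, 1, 1],
        [2, 1, 2, 2, 1, 1, 1, 1, 2, 1, 1, 2, 1],
        [3, 3, 1, 3, 3, 3, 3, 3, 4, 3, 3, 3, 3],
        [2, 1, 2, 2, 1, 1, 1, 1, 2, 1, 1, 2, 1],
    ],
    dtype=np.int64,
)


def table1_fixture() -> DecisionTable:
    """The bundled 15-patient urological sample table."""
    return DecisionTable(_SAMPLE_ROWS[:, :-1].copy(), _SAMPLE_ROWS[:, -1].copy())


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible synthetic decision table.

    In ``consistent`` mode the decision is a deterministic (seeded lookup)
    function of the ``planted_reduct`` columns, so that subset — and hence
    the full attribute set — has dependency 1.  With ``ensure_minimal`` the
    generator additionally resamples until no proper subset of the planted
    reduct keeps dependency 1, making it a genuine minimal reduct.  In
    ``inject_conflicts`` mode a fraction of rows is duplicated with a
    changed decision, forcing dependency of the full attribute set below 1.
    """

    n_rows: int
    n_attrs: int
    n_value_levels: int = 4
    n_classes: int = 3
    consistency_mode: str = "consistent"  # or "inject_conflicts"
    conflict_fraction: float = 0.2
    planted_reduct: tuple[int, ...] | None = None
    ensure_minimal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("n_rows must be >= 2")
        if self.n_attrs < 1:
            raise ValueError("n_attrs must be >= 1")
        if self.consistency_mode not in ("consistent", "inject_conflicts"):
            raise ValueError(f"unknown consistency_mode {self.consistency_mode!r}")
        if not 0 <= self.conflict_fraction < 1:
            raise ValueError("conflict_fraction must be in [0, 1)")
        if self.planted_reduct is not None:
            reduct = tuple(sorted(set(int(i) for i in self.planted_reduct)))
            if reduct and (reduct[0] < 0 or reduct[-1] >= self.n_attrs):
                raise ValueError("planted reduct index out of range")
            object.__setattr__(self, "planted_reduct", reduct)


def _projection_gamma(rows: np.ndarray, decisions: np.ndarray, subset: Sequence[int]) -> float:
    """Dependency of a column subset (local helper; the rough_core module is
    the user-facing implementation and cross-checks this in tests)."""
    if not subset:
        return float(len(set(decisions.tolist())) == 1)
    proj = rows[:, list(subset)]
    _, inverse = np.unique(proj, axis=0, return_inverse=True)
    pos = 0
    for block in range(inverse.max() + 1):
        members = decisions[inverse == block]
        if len(set(members.tolist())) == 1:
            pos += members.size
    return pos / rows.shape[0]


def synthesize_table(spec: SyntheticSpec, max_attempts: int = 500) -> DecisionTable:
    """Generate a decision table per ``spec``; identical seeds give identical tables."""
    rng = np.random.default_rng(spec.seed)
    reduct = spec.planted_reduct if spec.planted_reduct is not None else tuple(range(spec.n_attrs))
    for _ in range(max_attempts):
        rows = rng.integers(1, spec.n_value_levels + 1, size=(spec.n_rows, spec.n_attrs))
        # Seeded lookup: every possible reduct projection gets a random class.
        n_cells = spec.n_value_levels ** len(reduct)
        lookup = rng.integers(1, spec.n_classes + 1, size=n_cells)
        key = np.zeros(spec.n_rows, dtype=np.int64)
        for col in reduct:
            key = key * spec.n_value_levels + (rows[:, col] - 1)
        decisions = lookup[key]
        if len(set(decisions.tolist())) < min(2, spec.n_classes):
            continue
        if spec.ensure_minimal and reduct:
            ok = all(
                _projection_gamma(rows, decisions, [a for a in reduct if a != drop]) < 1.0
                for drop in reduct
            )
            if not ok:
                continue
        break
    else:
        raise RuntimeError("could not realize the requested synthetic table; relax the spec")

    if spec.consistency_mode == "inject_conflicts":
        n_conflict = max(1, int(round(spec.conflict_fraction * spec.n_rows)))
        picks = rng.choice(spec.n_rows, size=n_conflict, replace=False)
        extra_rows = rows[picks]
        shift = rng.integers(1, spec.n_classes, size=n_conflict) if spec.n_classes > 1 else np.ones(n_conflict, dtype=np.int64)
        extra_dec = (decisions[picks] - 1 + shift) % spec.n_classes + 1
        rows = np.vstack([rows, extra_rows])
        decisions = np.concatenate([decisions, extra_dec])

    return DecisionTable(rows, decisions)
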