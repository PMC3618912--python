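import numpy as np
import pytest

from roughsel.decision_table import DecisionTable, table1_fixture


@pytest.fixture
def table1() -> DecisionTable:
    return table1_fixture()


def random_table(rng: np.random.Generator, n_rows: int, n_attrs: int,
                 n_levels: int = 4, n_classes: int = 3) -> DecisionTable:
    """Unconstrained random table; decisions independent of attributes, so
    inconsistent blocks are common."""
    rows = rng.integers(1, n_levels + 1, size=(n_rows, n_attrs))
    decisions = rng.integers(1, n_classes + 1, size=n_rows)
    return DecisionTable(rows, decisions)


def random_consistent_table(rng: np.random.Generator, n_rows: int, n_attrs: int,
                            n_levels: int = 3) -> DecisionTable:
    """Random table whose decision is a function of all attribute columns."""
    from roughsel.decision_table import SyntheticSpec, synthesize_table

    spec = SyntheticSpec(
        n_rows=n_rows, n_attrs=n_attrs, n_value_levels=n_levels,
        seed=int(rng.integers(0, 2**31)),
    )
    return synthesize_table(spec)
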