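"""Simulated contingency-table series and bootstrap resampling.

Two ways of producing the repeat series behind the input matrix Z:

* `simulate_series` draws t independent multinomial tables (default:
  independent variables with uniform cell probabilities — no true
  association, so all measures hover near small positive values);
* `bootstrap_tables` draws t with-replacement resamples of a raw
  two-column categorical dataset and cross-tabulates each at fixed shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable
from .measures import METHOD_LABELS, Direction, compute_all
from .meta import InputMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "CategoricalDataset",
    "simulate_table",
    "simulate_series",
    "bootstrap_indices",
    "bootstrap_tables",
    "build_input_matrix",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Design of a simulated table series.

    Defaults mirror the standard study conditions: N = 1000 observations
    per table, t = 1000 repeats, independent variables with uniform cell
    probabilities.  ``cell_probs`` may supply any r x c joint probability
    matrix to inject association.
    """

    r: int = 2
    c: int = 3
    n: int = 1000
    t: int = 1000
    cell_probs: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 2 or self.c < 2:
            raise ValueError("table shape must be at least 2 x 2")
        if self.n < 1 or self.t < 1:
            raise ValueError("n and t must be >= 1")
        if self.cell_probs is not None:
            p = np.asarray(self.cell_probs, dtype=float)
            if p.shape != (self.r, self.c):
                raise ValueError("cell_probs shape must match (r, c)")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("cell_probs must be a probability matrix summing to 1")

    def probs(self) -> np.ndarray:
        if self.cell_probs is not None:
            return np.asarray(self.cell_probs, dtype=float)
        return np.full((self.r, self.c), 1.0 / (self.r * self.c))


@dataclass(frozen=True)
class CategoricalDataset:
    """Raw paired categorical observations with fixed level sets."""

    rows: tuple
    cols: tuple
    row_levels: tuple
    col_levels: tuple

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.cols):
            raise ValueError("row and column observations must align")
        if not set(self.rows) <= set(self.row_levels):
            raise ValueError("row observation outside declared levels")
        if not set(self.cols) <= set(self.col_levels):
            raise ValueError("column observation outside declared levels")

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_csv(cls, path, row_var: str, col_var: str) -> "CategoricalDataset":
        """Load two named columns of a CSV of raw observations."""
        df = pd.read_csv(path)
        for name in (row_var, col_var):
            if name not in df.columns:
                raise ValueError(f"column {name!r} not found in {path}")
        rows = tuple(df[row_var].astype(str))
        cols = tuple(df[col_var].astype(str))
        return cls(
            rows=rows,
            cols=cols,
            row_levels=tuple(sorted(set(rows))),
            col_levels=tuple(sorted(set(cols))),
        )

    def to_table(self) -> ContingencyTable:
        return ContingencyTable.from_observations(
            self.rows, self.cols, self.row_levels, self.col_levels
        )


def simulate_table(spec: SimulationSpec, index: int) -> ContingencyTable:
    """One multinomial table draw; deterministic given (spec.seed, index)."""
    rng = np.random.default_rng([spec.seed, index])
    flat = rng.multinomial(spec.n, spec.probs().ravel())
    return ContingencyTable(flat.reshape(spec.r, spec.c))


def simulate_series(spec: SimulationSpec) -> list[ContingencyTable]:
    """The full series of t independent table draws."""
    return [simulate_table(spec, k) for k in range(spec.t)]


def bootstrap_indices(size: int, t: int, seed: int = 0) -> np.ndarray:
    """t rows of ``size`` with-replacement draws from range(size) — the
    index plan behind :func:`bootstrap_tables`, exposed for inspection."""
    if size < 1:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    return rng.integers(0, size, size=(t, size))


def bootstrap_tables(
    data: CategoricalDataset, t: int, seed: int = 0
) -> list[ContingencyTable]:
    """t with-replacement resamples of the dataset, each cross-tabulated at
    the dataset's fixed level sets (absent levels keep zero rows/columns)."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    rows = np.asarray(data.rows, dtype=object)
    cols = np.asarray(data.cols, dtype=object)
    plan = bootstrap_indices(len(data), t, seed)
    return [
        ContingencyTable.from_observations(
            rows[idx], cols[idx], data.row_levels, data.col_levels
        )
        for idx in plan
    ]


def build_input_matrix(
    tables: Sequence[ContingencyTable],
    direction: Direction = "row-given-column",
    bias_correct: bool = False,
) -> InputMatrix:
    """Assemble Z (7 x t) by applying all measures to each table.

    Repeats on which any measure is undefined (degenerate resample with a
    constant variable) are dropped, with the count logged and carried on
    the returned matrix.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    columns = []
    dropped = 0
    for table in tables:
        vec = compute_all(table, direction=direction, bias_correct=bias_correct)
        if vec.complete:
            columns.append(vec.as_array())
        else:
            dropped += 1
    if not columns:
        raise ValueError("all repeats dropped: every table was degenerate")
    if dropped:
        logger.info("dropped %d/%d degenerate repeats from Z", dropped, len(tables))
    z = np.column_stack(columns)
    return InputMatrix(z, method_labels=METHOD_LABELS, n_dropped=dropped)
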