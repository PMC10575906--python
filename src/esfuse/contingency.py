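"""Contingency tables and the shared chi-square machinery.

An r x c contingency table of joint counts of two categorical variables is
the universal input of every effect-size measure in this package.  The table
carries its margins and knows how to compute the Pearson chi-square statistic
against the independence model, which underlies Cramér's V, Tschuprow's T,
Pearson's contingency coefficient and Cohen's w.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

__all__ = ["ContingencyTable", "ChiSquareStats"]


@dataclass(frozen=True)
class ChiSquareStats:
    """Pearson chi-square statistic and derived quantities for one table.

    Attributes
    ----------
    chi2 : float
        Pearson chi-square statistic, ``sum((O - E)^2 / E)`` over cells with
        positive expected count.  Zero iff observed counts equal the expected
        counts under independence.
    phi2 : float
        ``chi2 / n`` — the squared mean-square contingency (phi squared).
    n, r, c : int
        Total count and table shape, copied from the source table.
    """

    chi2: float
    phi2: float
    n: int
    r: int
    c: int


class ContingencyTable:
    """An r x c table of non-negative integer joint counts.

    Parameters
    ----------
    counts : array-like of shape (r, c)
        Non-negative integer cell counts; at least a 2 x 2 layout, with a
        grand total of at least one observation.

    Examples
    --------
    >>> t = ContingencyTable([[10, 20], [30, 40]])
    >>> t.n, t.r, t.c
    (100, 2, 2)
    >>> round(t.chi_square().chi2, 4)
    0.7937
    """

    def __init__(self, counts) -> None:
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if arr.size == 0:
            raise ValueError("counts must be non-empty")
        if np.any(arr < 0):
            raise ValueError("all cells must be non-negative")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("all cells must be finite")
        if np.any(arr != np.floor(arr)):
            raise ValueError("all cells must be integers")
        self.counts = arr.astype(np.int64)
        if self.counts.sum() < 1:
            raise ValueError("empty table: grand total must be at least 1")

    # -- basic structure ---------------------------------------------------

    @property
    def r(self) -> int:
        return self.counts.shape[0]

    @property
    def c(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ContingencyTable(r={self.r}, c={self.c}, n={self.n})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ContingencyTable) and np.array_equal(
            self.counts, other.counts
        )

    # -- chi-square machinery ----------------------------------------------

    def expected(self) -> np.ndarray:
        """Expected counts under independence, from the observed margins."""
        return expected_freq(self.counts)

    def chi_square(self) -> ChiSquareStats:
        """Pearson chi-square against independence.

        Cells whose expected count is zero (an all-zero row or column, as
        arises on degenerate bootstrap resamples kept at fixed shape) carry
        no information about association and are skipped in the sum.
        """
        if np.all(self.counts == 0):
            raise ValueError("empty table")
        exp = self.expected()
        mask = exp > 0
        obs = self.counts[mask].astype(float)
        chi2 = float(np.sum((obs - exp[mask]) ** 2 / exp[mask]))
        return ChiSquareStats(chi2=chi2, phi2=chi2 / self.n, n=self.n, r=self.r, c=self.c)

    def is_degenerate(self) -> bool:
        """True when fewer than two rows or columns hold any mass."""
        return (np.count_nonzero(self.row_totals) < 2) or (
            np.count_nonzero(self.col_totals) < 2
        )

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_observations(
        cls,
        rows,
        cols,
        row_levels=None,
        col_levels=None,
    ) -> "ContingencyTable":
        """Cross-tabulate paired categorical observations.

        ``row_levels`` / ``col_levels`` fix the table layout so that levels
        absent from a particular sample keep a zero row/column — resamples of
        the same data then share a common shape.
        """
        rows = pd.Categorical(rows, categories=row_levels)
        cols = pd.Categorical(cols, categories=col_levels)
        tab = pd.crosstab(rows, cols, dropna=False)
        return cls(tab.to_numpy())

    @classmethod
    def from_csv(cls, path_or_buffer) -> "ContingencyTable":
        """Read a table from CSV: a plain numeric grid, with an optional
        header line and optional leading row-label column auto-detected."""
        if hasattr(path_or_buffer, "read"):
            text = path_or_buffer.read()
        else:
            with open(path_or_buffer, "r", encoding="utf-8") as fh:
                text = fh.read()
        df = pd.read_csv(io.StringIO(text), header=None)
        # drop a header row / label column if they are non-numeric
        first_row_numeric = pd.to_numeric(df.iloc[0], errors="coerce").notna().all()
        if not first_row_numeric:
            df = df.iloc[1:]
        first_col_numeric = pd.to_numeric(df.iloc[:, 0], errors="coerce").notna().all()
        if not first_col_numeric:
            df = df.iloc[:, 1:]
        return cls(df.astype(float).to_numpy())
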