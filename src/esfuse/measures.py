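"""Seven categorical effect-size measures for r x c contingency tables.

Four of the measures are functions of the Pearson chi-square statistic
(Cramér's V, Tschuprow's T, Pearson's contingency coefficient, Cohen's w)
and three are prediction-based association measures (Goodman–Kruskal tau,
Theil's uncertainty coefficient U, Goodman–Kruskal lambda).  All live on a
common [0, 1] scale — except Cohen's w, which can exceed 1 on tables with
more than two levels of association — which is what makes them combinable
downstream.

Directional measures (tau, U, lambda) default to the row-given-column
convention: the row variable is treated as the dependent variable to be
predicted from the column variable.

Useful algebraic identities (independence model, full table):

    w = sqrt(chi2 / n) = phi
    c = w / sqrt(1 + w^2)
    V = w / sqrt(min(r - 1, c - 1))
    T = w / ((r - 1) (c - 1))^(1/4)
    tau = phi^2           (on 2 x 2 tables)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .contingency import ContingencyTable

__all__ = [
    "METHOD_ORDER",
    "EffectSizeVector",
    "cramers_v",
    "tschuprows_t",
    "pearsons_c",
    "cohens_w",
    "gk_tau",
    "uncertainty_coefficient",
    "gk_lambda",
    "compute_all",
    "pearsons_c_from_w",
    "tschuprows_t_from_w",
]

#: Fixed method order of the input matrix Z and every weight vector.
METHOD_ORDER = (
    "cramers_v",
    "pearsons_c",
    "tschuprows_t",
    "cohens_w",
    "gk_tau",
    "uncertainty_u",
    "gk_lambda",
)

#: Human-readable labels, index-aligned with METHOD_ORDER.
METHOD_LABELS = (
    "Cramer's v",
    "Pearson's c",
    "Tschuprow's T",
    "Cohen's w",
    "G-K Tau",
    "U",
    "lambda",
)

Direction = Literal["row-given-column", "column-given-row"]


@dataclass(frozen=True)
class EffectSizeVector:
    """The seven measures for one table, in the fixed METHOD_ORDER.

    Measures that are undefined on a degenerate table (constant variable)
    are recorded as NaN; downstream assembly drops such repeats.
    """

    cramers_v: float
    pearsons_c: float
    tschuprows_t: float
    cohens_w: float
    gk_tau: float
    uncertainty_u: float
    gk_lambda: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.cramers_v,
                self.pearsons_c,
                self.tschuprows_t,
                self.cohens_w,
                self.gk_tau,
                self.uncertainty_u,
                self.gk_lambda,
            ]
        )

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


def _require_nondegenerate(table: ContingencyTable) -> None:
    if table.r < 2 or table.c < 2:
        raise ValueError("degenerate table: need at least 2 rows and 2 columns")


# ---------------------------------------------------------------------------
# chi-square based measures


def cohens_w(table: ContingencyTable) -> float:
    """Cohen's w: root mean-square discrepancy between observed and
    independence cell proportions; algebraically sqrt(chi2 / n)."""
    _require_nondegenerate(table)
    return math.sqrt(table.chi_square().phi2)


def cramers_v(table: ContingencyTable, bias_correct: bool = False) -> float:
    """Cramér's V, ``sqrt(phi^2 / min(c - 1, r - 1))``.

    With ``bias_correct=True`` the Bergsma small-sample correction is
    applied: phi^2 is shrunk by its expectation under independence and the
    effective numbers of rows and columns are reduced accordingly.
    """
    _require_nondegenerate(table)
    stats = table.chi_square()
    r, c, n = stats.r, stats.c, stats.n
    if not bias_correct:
        return math.sqrt(stats.phi2 / min(c - 1, r - 1))
    if n <= 1:
        raise ValueError("bias correction requires n > 1")
    phi2_corr = max(0.0, stats.phi2 - (r - 1) * (c - 1) / (n - 1))
    r_corr = r - (r - 1) ** 2 / (n - 1)
    c_corr = c - (c - 1) ** 2 / (n - 1)
    denom = min(r_corr - 1, c_corr - 1)
    return math.sqrt(phi2_corr / denom)


def tschuprows_t(table: ContingencyTable) -> float:
    """Tschuprow's T, ``sqrt(phi^2 / sqrt((r - 1)(c - 1)))`` — the standard
    fourth-root normalisation, which equals Cramér's V on square tables."""
    _require_nondegenerate(table)
    stats = table.chi_square()
    return math.sqrt(stats.phi2 / math.sqrt((stats.r - 1) * (stats.c - 1)))


def pearsons_c(table: ContingencyTable) -> float:
    """Pearson's contingency coefficient, ``sqrt(chi2 / (chi2 + n))``;
    strictly below 1 for any finite table."""
    _require_nondegenerate(table)
    stats = table.chi_square()
    return math.sqrt(stats.chi2 / (stats.chi2 + stats.n))


def pearsons_c_from_w(w: float, n: int) -> float:
    """Pearson's c recovered from Cohen's w at sample size n.

    Identity: chi2 = n w^2, hence c = sqrt(n w^2 / (n w^2 + n)) =
    w / sqrt(1 + w^2) — independent of n, which only enters through chi2.
    """
    chi2 = n * w * w
    return math.sqrt(chi2 / (chi2 + n))


def tschuprows_t_from_w(w: float, r: int, c: int) -> float:
    """Tschuprow's T recovered from Cohen's w for an r x c table."""
    return w / ((r - 1) * (c - 1)) ** 0.25


# ---------------------------------------------------------------------------
# prediction-based measures


def _oriented(table: ContingencyTable, direction: Direction) -> np.ndarray:
    if direction == "row-given-column":
        return table.counts.astype(float)
    if direction == "column-given-row":
        return table.counts.T.astype(float)
    raise ValueError(f"unknown direction: {direction!r}")


def gk_tau(
    table: ContingencyTable, direction: Direction = "row-given-column"
) -> float:
    """Goodman–Kruskal tau: proportional reduction in the probability of a
    classification error when predicting the dependent variable from the
    other one, using squared cell probabilities."""
    _require_nondegenerate(table)
    a = _oriented(table, direction)
    n = a.sum()
    row_tot = a.sum(axis=1)
    col_tot = a.sum(axis=0)
    denom = n * n - np.sum(row_tot**2)
    if denom <= 0:
        raise ValueError("tau undefined: dependent variable is constant")
    pos = col_tot > 0
    num = n * np.sum(a[:, pos] ** 2 / col_tot[pos]) - np.sum(row_tot**2)
    return float(num / denom)


def uncertainty_coefficient(
    table: ContingencyTable, direction: Direction = "row-given-column"
) -> float:
    """Theil's uncertainty coefficient U = I(X;Y) / H(X): the fraction of
    the dependent variable's entropy explained by the other variable.
    Invariant to the logarithm base; 0 log 0 terms are treated as 0."""
    _require_nondegenerate(table)
    a = _oriented(table, direction)
    n = a.sum()
    p_x = a.sum(axis=1) / n  # dependent marginal
    p_y = a.sum(axis=0) / n
    h_x = -np.sum(p_x[p_x > 0] * np.log(p_x[p_x > 0]))
    if h_x <= 0:
        raise ValueError("U undefined: dependent variable is constant")
    # H(X|Y) = -sum_xy p(x,y) log p(x|y)
    h_xy = 0.0
    for j in range(a.shape[1]):
        if p_y[j] <= 0:
            continue
        p_joint = a[:, j] / n
        p_cond = a[:, j] / a[:, j].sum()
        nz = p_joint > 0
        h_xy -= np.sum(p_joint[nz] * np.log(p_cond[nz]))
    return float((h_x - h_xy) / h_x)


def gk_lambda(
    table: ContingencyTable, direction: Direction = "row-given-column"
) -> float:
    """Goodman–Kruskal lambda: proportional reduction of modal-prediction
    errors.  E1 = n - max row total (errors ignoring the predictor),
    E2 = sum over columns of (column total - column maximum)."""
    _require_nondegenerate(table)
    a = _oriented(table, direction)
    n = a.sum()
    e1 = n - a.sum(axis=1).max()
    if e1 <= 0:
        raise ValueError("lambda undefined: one category holds all mass")
    e2 = np.sum(a.sum(axis=0) - a.max(axis=0))
    return float((e1 - e2) / e1)


# ---------------------------------------------------------------------------


def compute_all(
    table: ContingencyTable,
    direction: Direction = "row-given-column",
    bias_correct: bool = False,
) -> EffectSizeVector:
    """All seven measures for one table, NaN-flagging any that are undefined
    on a degenerate table instead of raising."""

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError:
            return float("nan")

    return EffectSizeVector(
        cramers_v=_try(cramers_v, table, bias_correct=bias_correct),
        pearsons_c=_try(pearsons_c, table),
        tschuprows_t=_try(tschuprows_t, table),
        cohens_w=_try(cohens_w, table),
        gk_tau=_try(gk_tau, table, direction=direction),
        uncertainty_u=_try(uncertainty_coefficient, table, direction=direction),
        gk_lambda=_try(gk_lambda, table, direction=direction),
    )
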