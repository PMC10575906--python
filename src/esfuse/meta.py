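"""Meta fuzzy effect-size functions: clustering-weighted combinations of
categorical association measures.

The idea is forecast combination applied to effect sizes.  Each of the m
measures produces a series of values over t resamples or simulated tables
(the input matrix Z, m x t).  The measures — viewed as points in t-dimensional
space — are clustered with intuitionistic fuzzy c-means; within each cluster
the adjusted membership grades, normalised to sum to one, become the weights
of a convex combination of the measures ("meta fuzzy function").  Functions
are scored by mean absolute percentage error (MAPE) against the cross-method
mean series, the cluster count is searched over a small range, and the
function with minimal MAPE supplies the weights of the final combined effect
size.

The module follows the statsmodels convention: build a
:class:`MetaEffectSizeModel` from data, call :meth:`~MetaEffectSizeModel.fit`,
and read estimates and diagnostics off the returned
:class:`MetaEffectSizeResults` (or print its :meth:`summary`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable
from .ifcm import ClusterConfig, ClusteringResult, ifcm
from .measures import METHOD_LABELS, METHOD_ORDER, Direction, EffectSizeVector, compute_all

logger = logging.getLogger(__name__)

__all__ = [
    "InputMatrix",
    "MetaEffectSizeModel",
    "MetaEffectSizeResults",
    "build_weights",
    "truth_series",
    "evaluate_functions",
    "mape",
    "relative_bias",
    "select_best",
    "combine_effect_size",
]


@dataclass(frozen=True)
class InputMatrix:
    """The m x t matrix Z of effect-size values: m measures (rows, fixed
    order) by t repeats (columns).  Entries are finite and non-negative;
    repeats on which any measure was undefined have already been dropped."""

    z: np.ndarray
    method_labels: tuple = METHOD_LABELS
    n_dropped: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2:
            raise ValueError("Z must be 2-D (methods x repeats)")
        if z.shape[0] != len(self.method_labels):
            raise ValueError("row count must match method labels")
        if not np.all(np.isfinite(z)):
            raise ValueError("Z must be finite")
        if np.any(z < 0):
            raise ValueError("Z must be non-negative")
        object.__setattr__(self, "z", z)

    @property
    def m(self) -> int:
        return self.z.shape[0]

    @property
    def t(self) -> int:
        return self.z.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z,
            index=list(self.method_labels),
            columns=[f"t_{k + 1}" for k in range(self.t)],
        )


# ---------------------------------------------------------------------------
# elemental operations


def build_weights(mu_star: np.ndarray) -> np.ndarray:
    """Per-cluster weights: each cluster's adjusted membership grades over
    the m methods, normalised to sum to one."""
    mu_star = np.asarray(mu_star, dtype=float)
    if np.any(mu_star < 0):
        raise ValueError("mu_star must be non-negative")
    totals = mu_star.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("degenerate cluster: all-zero membership row")
    return mu_star / totals[:, None]


def truth_series(z: InputMatrix | np.ndarray) -> np.ndarray:
    """Reference series: the per-repeat mean of the m method values."""
    arr = z.z if isinstance(z, InputMatrix) else np.asarray(z, dtype=float)
    return arr.mean(axis=0)


def evaluate_functions(z: InputMatrix | np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Predictions of the c meta functions at each repeat: weights @ Z."""
    arr = z.z if isinstance(z, InputMatrix) else np.asarray(z, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[1] != arr.shape[0]:
        raise ValueError(
            f"weight columns ({weights.shape[1]}) must match method count ({arr.shape[0]})"
        )
    return weights @ arr


def _guard_zero_truth(actual: np.ndarray, predicted: np.ndarray):
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("series length mismatch")
    keep = actual != 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d zero-truth repeats from MAPE/bias", dropped)
    if not keep.any():
        raise ValueError("no repeats left after dropping zero-truth values")
    return actual[keep], predicted[keep], dropped


def mape(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute percentage error, (1/t) sum |y - yhat| / y.

    Repeats with zero truth are dropped (and counted in the log)."""
    y, yhat, _ = _guard_zero_truth(actual, predicted)
    return float(np.mean(np.abs(y - yhat) / y))


def relative_bias(actual: np.ndarray, predicted: np.ndarray, absolute: bool = False) -> float:
    """Mean relative deviation of predictions from truth,
    (1/t) sum (yhat - y) / y; negative when predictions run below truth.
    ``absolute=True`` returns the mean absolute relative deviation instead."""
    y, yhat, _ = _guard_zero_truth(actual, predicted)
    rel = (yhat - y) / y
    return float(np.mean(np.abs(rel) if absolute else rel))


def select_best(mape_values: Sequence[float]) -> int:
    """Index of the minimum MAPE; ties broken by lowest index."""
    arr = np.asarray(mape_values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one function")
    return int(np.argmin(arr))


def combine_effect_size(weights_best: np.ndarray, es: EffectSizeVector | np.ndarray) -> float:
    """Combined effect size: the convex combination of the seven measure
    values under the best function's weights."""
    w = np.asarray(weights_best, dtype=float)
    values = es.as_array() if isinstance(es, EffectSizeVector) else np.asarray(es, dtype=float)
    if w.shape != values.shape:
        raise ValueError("weights and effect sizes must align")
    # tolerance admits weight vectors rounded for display (4 d.p.)
    if not np.isclose(w.sum(), 1.0, atol=1e-3):
        raise ValueError("weights must sum to 1")
    return float(w @ values)


# ---------------------------------------------------------------------------
# model / results


class MetaEffectSizeModel:
    """Adaptive combiner of categorical effect-size measures.

    Parameters
    ----------
    z : InputMatrix, ndarray or DataFrame
        The m x t input matrix of effect-size values (methods as rows in
        the fixed order, repeats as columns).
    config : ClusterConfig, optional
        IFCM hyper-parameters (fuzziness f, intuitionistic exponent alpha,
        convergence threshold, seed).

    Examples
    --------
    >>> from esfuse.datagen import SimulationSpec, simulate_series
    >>> from esfuse.meta import MetaEffectSizeModel
    >>> tables = simulate_series(SimulationSpec(r=2, c=3, n=1000, t=50, seed=7))
    >>> res = MetaEffectSizeModel.from_tables(tables).fit()
    >>> res.best_mape <= res.mape_.max()
    True
    """

    def __init__(self, z, config: ClusterConfig | None = None) -> None:
        if isinstance(z, pd.DataFrame):
            z = InputMatrix(z.to_numpy(), method_labels=tuple(z.index))
        elif not isinstance(z, InputMatrix):
            z = InputMatrix(np.asarray(z, dtype=float))
        self.z = z
        self.config = config or ClusterConfig()

    @classmethod
    def from_tables(
        cls,
        tables: Sequence[ContingencyTable],
        direction: Direction = "row-given-column",
        bias_correct: bool = False,
        config: ClusterConfig | None = None,
    ) -> "MetaEffectSizeModel":
        """Build the input matrix by applying all seven measures to each
        table; repeats with any undefined measure are dropped and logged."""
        from .datagen import build_input_matrix  # local import, no cycle at runtime

        return cls(
            build_input_matrix(tables, direction=direction, bias_correct=bias_correct),
            config=config,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ClusterConfig | None = None):
        return cls(df, config=config)

    def fit(self, c_range: tuple[int, int] = (2, 5)) -> "MetaEffectSizeResults":
        """Search the cluster count over ``c_range`` (inclusive), score each
        candidate's best function by MAPE against the cross-method mean, and
        return the results for the winning cluster count.

        Ties on MAPE are broken toward the smaller cluster count.
        """
        c_min, c_max = c_range
        if c_min < 1 or c_max > self.z.m:
            raise ValueError(f"c_range must lie within [1, {self.z.m}]")
        if c_min > c_max:
            raise ValueError("c_range must be increasing")

        y = truth_series(self.z)
        search: list[tuple[int, float]] = []
        best_pack = None
        for c in range(c_min, c_max + 1):
            cfg = ClusterConfig(
                c=c,
                f=self.config.f,
                alpha=self.config.alpha,
                epsilon=self.config.epsilon,
                max_iter=self.config.max_iter,
                seed=self.config.seed,
            )
            clustering = ifcm(self.z.z, cfg)
            weights = build_weights(clustering.mu_star)
            preds = evaluate_functions(self.z, weights)
            mapes = np.array([mape(y, preds[i]) for i in range(c)])
            biases = np.array([relative_bias(y, preds[i]) for i in range(c)])
            idx = select_best(mapes)
            search.append((c, float(mapes[idx])))
            logger.info("c=%d: best-function MAPE %.4f", c, mapes[idx])
            if best_pack is None or mapes[idx] < best_pack[0]:
                best_pack = (float(mapes[idx]), c, clustering, weights, preds, mapes, biases, idx)

        _, c_star, clustering, weights, preds, mapes, biases, idx = best_pack
        method_mape = np.array([mape(y, self.z.z[j]) for j in range(self.z.m)])
        method_bias = np.array([relative_bias(y, self.z.z[j]) for j in range(self.z.m)])
        return MetaEffectSizeResults(
            model=self,
            n_clusters=c_star,
            clustering=clustering,
            weights=weights,
            predictions=preds,
            mape_=mapes,
            bias_=biases,
            best_index=idx,
            truth=y,
            method_mape=method_mape,
            method_bias=method_bias,
            cluster_search=search,
        )


@dataclass
class MetaEffectSizeResults:
    """Fitted meta-function set: weights, diagnostics and the best function.

    Attributes
    ----------
    n_clusters : int
        The winning cluster count from the search.
    weights : ndarray (c, m)
        Normalised adjusted-membership weights; rows sum to one.
    predictions : ndarray (c, t)
        Each function's value at each repeat.
    mape_, bias_ : ndarray (c,)
        MAPE and mean relative bias of each function against the
        cross-method mean series.
    best_index : int
        Index of the minimal-MAPE function.
    method_mape, method_bias : ndarray (m,)
        The same diagnostics for each individual measure.
    """

    model: MetaEffectSizeModel
    n_clusters: int
    clustering: ClusteringResult
    weights: np.ndarray
    predictions: np.ndarray
    mape_: np.ndarray
    bias_: np.ndarray
    best_index: int
    truth: np.ndarray
    method_mape: np.ndarray
    method_bias: np.ndarray
    cluster_search: list = field(default_factory=list)

    @property
    def best_weights(self) -> np.ndarray:
        return self.weights[self.best_index]

    @property
    def best_mape(self) -> float:
        return float(self.mape_[self.best_index])

    @property
    def best_bias(self) -> float:
        return float(self.bias_[self.best_index])

    def combine(self, es: EffectSizeVector | np.ndarray) -> float:
        """Combined effect size for a target table's measure vector under
        the best function's weights."""
        return combine_effect_size(self.best_weights, es)

    def weights_frame(self) -> pd.DataFrame:
        labels = list(self.model.z.method_labels)
        return pd.DataFrame(
            self.weights.T,
            index=labels,
            columns=[f"function_{i + 1}" for i in range(self.n_clusters)],
        )

    def method_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"MAPE": self.method_mape, "bias": self.method_bias},
            index=list(self.model.z.method_labels),
        )

    def to_dict(self) -> dict:
        """Full-precision serialisable report."""
        return {
            "n_clusters": self.n_clusters,
            "cluster_search": [{"c": c, "best_mape": m} for c, m in self.cluster_search],
            "method_labels": list(self.model.z.method_labels),
            "weights": self.weights.tolist(),
            "function_mape": self.mape_.tolist(),
            "function_bias": self.bias_.tolist(),
            "best_index": int(self.best_index),
            "best_weights": self.best_weights.tolist(),
            "best_mape": self.best_mape,
            "best_bias": self.best_bias,
            "method_mape": self.method_mape.tolist(),
            "method_bias": self.method_bias.tolist(),
            "n_repeats": int(self.model.z.t),
            "n_dropped_repeats": int(self.model.z.n_dropped),
            "ifcm_converged": bool(self.clustering.converged),
            "ifcm_iterations": int(self.clustering.iterations),
        }

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = []
        lines.append("Meta fuzzy effect-size combination")
        lines.append("=" * 58)
        lines.append(f"repeats (t):        {self.model.z.t}")
        lines.append(f"clusters searched:  {[c for c, _ in self.cluster_search]}")
        lines.append(f"selected clusters:  {self.n_clusters}")
        lines.append(f"best function:      {self.best_index + 1}")
        lines.append(f"best MAPE:          {self.best_mape:.4f}")
        lines.append(f"best bias:          {self.best_bias:+.4f}")
        lines.append("-" * 58)
        lines.append(f"{'measure':<16}" + "".join(
            f"w_fn{i + 1:<6}" for i in range(self.n_clusters)
        ) + f"{'MAPE':>8}{'bias':>9}")
        for j, label in enumerate(self.model.z.method_labels):
            wcols = "".join(f"{self.weights[i, j]:<9.4f}" for i in range(self.n_clusters))
            lines.append(
                f"{label:<16}{wcols}{self.method_mape[j]:>8.4f}{self.method_bias[j]:>+9.4f}"
            )
        lines.append("-" * 58)
        fn_mapes = "  ".join(f"{m:.4f}" for m in self.mape_)
        lines.append(f"function MAPE:      {fn_mapes}")
        return "\n".join(lines)
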