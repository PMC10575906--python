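"""Intuitionistic fuzzy c-means (IFCM) clustering.

Classical fuzzy c-means assigns each object a membership grade in every
cluster.  The intuitionistic variant also carries a non-membership grade

    u = (1 - mu^alpha)^(1/alpha),      alpha > 0,

which encodes the hesitancy of an object's assignment, and drives the
center update with the adjusted membership mu* = 1 - u instead of mu.
At alpha = 1 the adjustment is the identity (mu* = mu) and the algorithm
reduces to classical FCM, which makes that setting a convenient oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterConfig",
    "ClusteringResult",
    "memberships",
    "intuitionistic_adjust",
    "update_centers",
    "ifcm",
]


@dataclass(frozen=True)
class ClusterConfig:
    """IFCM hyper-parameters.

    Attributes
    ----------
    c : int
        Number of clusters (>= 1, and at most the number of objects).
    f : float
        Fuzziness index, > 1.  Larger values blur cluster boundaries;
        2 is the conventional choice.
    alpha : float
        Intuitionistic exponent of the non-membership transform, > 0.
        1 recovers classical FCM; 2 is the package default.
    epsilon : float
        Convergence threshold on the maximum absolute center displacement
        between iterations.
    max_iter : int
        Hard iteration cap.
    seed : int
        Seeds the choice of initial centers (c distinct objects drawn
        without replacement).
    """

    c: int = 2
    f: float = 2.0
    alpha: float = 2.0
    epsilon: float = 1e-6
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.f <= 1:
            raise ValueError("fuzziness index f must be > 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ClusteringResult:
    """Converged IFCM state: centers plus the full grade matrices."""

    centers: np.ndarray  # (c, d)
    mu: np.ndarray  # (c, n) membership
    u: np.ndarray  # (c, n) non-membership
    mu_star: np.ndarray  # (c, n) adjusted membership
    iterations: int
    converged: bool
    objective_trace: list = field(default_factory=list)  # center displacement per iter


def memberships(data: np.ndarray, centers: np.ndarray, f: float) -> np.ndarray:
    """Membership matrix mu (c x n) of objects in clusters.

    mu_ik = [ sum_j (d(x_k, v_i) / d(x_k, v_j))^(2/(f-1)) ]^(-1)

    with Euclidean d.  A zero-distance object gets crisp membership 1 in
    the coinciding cluster (and 0 elsewhere).  Columns sum to 1.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if f <= 1:
        raise ValueError("fuzziness index f must be > 1")
    c = centers.shape[0]
    # pairwise Euclidean distances, (c, n)
    diff = centers[:, None, :] - data[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    for i in range(c):
        for j in range(i + 1, c):
            if np.allclose(centers[i], centers[j], rtol=0.0, atol=0.0):
                raise ValueError("duplicate centers")
    n = data.shape[0]
    mu = np.empty((c, n))
    exponent = 2.0 / (f - 1.0)
    for k in range(n):
        d_k = dist[:, k]
        zero = d_k == 0.0
        if zero.any():
            mu[:, k] = 0.0
            mu[zero, k] = 1.0 / zero.sum()
        else:
            ratios = (d_k[:, None] / d_k[None, :]) ** exponent
            mu[:, k] = 1.0 / ratios.sum(axis=1)
    return mu


def intuitionistic_adjust(mu: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Non-membership u = (1 - mu^alpha)^(1/alpha) and adjusted membership
    mu* = 1 - u, elementwise.  Total on [0, 1]; exact at the endpoints."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("memberships must lie in [0, 1]")
    u = (1.0 - mu**alpha) ** (1.0 / alpha)
    return u, 1.0 - u


def update_centers(data: np.ndarray, mu_star: np.ndarray, f: float) -> np.ndarray:
    """Weighted-mean center update: v_i = sum_k (mu*_ik)^f x_k / sum_k (mu*_ik)^f."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    mu_star = np.asarray(mu_star, dtype=float)
    w = mu_star**f
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("empty cluster: zero total adjusted membership")
    return (w @ data) / totals[:, None]


def _init_centers(data: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Initial centers: c distinct objects, preferring distinct coordinates."""
    n = data.shape[0]
    unique_rows, first_idx = np.unique(data, axis=0, return_index=True)
    if unique_rows.shape[0] >= c:
        pick = rng.choice(unique_rows.shape[0], size=c, replace=False)
        return unique_rows[pick].copy()
    # fewer distinct points than clusters: fall back to distinct indices
    pick = rng.choice(n, size=c, replace=False)
    return data[pick].copy()


def ifcm(data: np.ndarray, config: ClusterConfig) -> ClusteringResult:
    """Run IFCM to convergence.

    Iterates membership -> intuitionistic adjustment -> center update until
    the maximum absolute center displacement drops below ``config.epsilon``
    or ``config.max_iter`` is reached.  Fully deterministic given
    ``config.seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input data")
    n = data.shape[0]
    if n < config.c:
        raise ValueError(f"need at least c={config.c} objects, got {n}")

    rng = np.random.default_rng(config.seed)
    centers = _init_centers(data, config.c, rng)

    trace: list[float] = []
    converged = False
    iterations = 0
    mu = memberships(data, centers, config.f)
    u, mu_star = intuitionistic_adjust(mu, config.alpha)
    for iterations in range(1, config.max_iter + 1):
        new_centers = update_centers(data, mu_star, config.f)
        shift = float(np.max(np.abs(new_centers - centers)))
        trace.append(shift)
        centers = new_centers
        mu = memberships(data, centers, config.f)
        u, mu_star = intuitionistic_adjust(mu, config.alpha)
        if shift < config.epsilon:
            converged = True
            break

    return ClusteringResult(
        centers=centers,
        mu=mu,
        u=u,
        mu_star=mu_star,
        iterations=iterations,
        converged=converged,
        objective_trace=trace,
    )
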