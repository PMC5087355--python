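"""Context-based fuzzy c-means (CFCM) clustering.

CFCM is fuzzy c-means with a per-point membership *budget*: instead of the
memberships of data point ``k`` summing to one across clusters, they sum to
the point's context membership ``w_k`` (a value in [0, 1] produced by a
triangular linguistic context on the residual axis).  Minimising

    Q = sum_i sum_k  u_ik^m * ||x_k - v_i||^2

subject to ``sum_i u_ik = w_k`` yields the alternating updates

    u_ik = w_k / sum_j (||x_k - v_i|| / ||x_k - v_j||)^(2/(m-1))
    v_i  = sum_k u_ik^m x_k / sum_k u_ik^m

Points with ``w_k = 0`` contribute nothing to the prototypes and keep
``u_ik = 0`` (they stay in the partition matrix for shape stability).
With ``w_k = 1`` for every point the procedure reduces exactly to standard
fuzzy c-means, which is the cross-check used in the test suite.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CFCMConfig",
    "CFCMResult",
    "ContextFuzzyCMeans",
    "cfcm_fit",
    "cfcm_objective",
]


@dataclass(frozen=True)
class CFCMConfig:
    """Iteration controls for CFCM.

    Parameters
    ----------
    m : float
        Fuzzification exponent; must be > 1.  2.0 is the conventional
        fuzzy-c-means default.
    max_iter : int
        Cap on the number of alternating update sweeps.
    tol : float
        Convergence tolerance on ``max |U_new - U_old|``.
    seed : int or None
        Seed for the random initial partition matrix.
    """

    m: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.m, numbers.Real) and self.m > 1):
            raise ValueError(f"fuzzification exponent m must be > 1, got {self.m}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class CFCMResult:
    """Outcome of one CFCM run within a single context.

    Attributes
    ----------
    U : ndarray of shape (c, N)
        Partition matrix; column ``k`` sums to the point's context
        membership ``w_k`` and ``0 <= u_ik <= w_k``.
    V : ndarray of shape (c, d)
        Cluster prototypes, each inside the convex hull of the positively
        weighted data.
    Q_trace : ndarray
        Objective value after each sweep; non-increasing.
    context_index : int
        Index of the context this run belongs to (-1 if standalone).
    """

    U: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)
    Q_trace: np.ndarray = field(repr=False)
    context_index: int = -1

    @property
    def n_clusters(self) -> int:
        return int(self.V.shape[0])


def cfcm_objective(X, U, V, m: float) -> float:
    """Weighted within-cluster scatter ``sum_ik u_ik^m ||x_k - v_i||^2``."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if X.ndim != 2 or U.ndim != 2 or V.ndim != 2:
        raise ValueError("X, U, V must be 2-D arrays")
    c, N = U.shape
    if X.shape[0] != N or V.shape != (c, X.shape[1]):
        raise ValueError(
            f"inconsistent shapes: X {X.shape}, U {U.shape}, V {V.shape}"
        )
    d2 = cdist(V, X, metric="sqeuclidean")
    return float(np.sum(U**m * d2))


def _init_partition(rng: np.random.Generator, c: int, w: np.ndarray) -> np.ndarray:
    """Random U with column sums equal to the context memberships w."""
    U = rng.random((c, w.size))
    colsum = U.sum(axis=0)
    return U * (w / colsum)


def _update_partition(X: np.ndarray, V: np.ndarray, w: np.ndarray, m: float) -> np.ndarray:
    """Membership update; coincident points get the full budget w_k,
    split equally across the prototypes at zero distance."""
    d2 = cdist(V, X, metric="sqeuclidean")  # (c, N)
    zero = d2 <= 0.0
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    U = np.where(np.isfinite(inv), inv, 0.0)
    has_zero = zero.any(axis=0)
    if has_zero.any():
        U[:, has_zero] = zero[:, has_zero] / zero[:, has_zero].sum(axis=0)
        denom = np.where(has_zero, 1.0, U.sum(axis=0))
    else:
        denom = U.sum(axis=0)
    return U / denom * w


def _update_prototypes(X: np.ndarray, U: np.ndarray, V_old: np.ndarray, m: float) -> np.ndarray:
    """Weighted-mean prototypes; a cluster whose memberships vanished keeps
    its previous prototype."""
    Um = U**m
    denom = Um.sum(axis=1)
    V = V_old.copy()
    pos = denom > 0
    V[pos] = (Um[pos] @ X) / denom[pos, None]
    return V


class ContextFuzzyCMeans(ClusterMixin, BaseEstimator):
    """Context-based fuzzy c-means clusterer.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of prototypes ``c`` within the context.
    m : float, default=2.0
        Fuzzification exponent (> 1).
    max_iter : int, default=100
        Maximum alternating-update sweeps.
    tol : float, default=1e-5
        Convergence threshold on ``max |U_new - U_old|``.
    random_state : int or None, default=None
        Seed for the random initial partition.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
        Fitted prototypes.
    membership_ : ndarray of shape (n_clusters, n_samples)
        Fitted partition matrix; column sums equal the context weights.
    objective_trace_ : ndarray
        Objective value per sweep (non-increasing).
    n_iter_ : int
        Sweeps actually performed.

    With ``context_weights`` omitted (all ones) the fit is standard fuzzy
    c-means.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        *,
        m: float = 2.0,
        max_iter: int = 100,
        tol: float = 1e-5,
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, context_weights=None) -> "ContextFuzzyCMeans":
        """Run the alternating CFCM updates to convergence.

        Parameters
        ----------
        X : array-like of shape (n_samples, n_features)
        context_weights : array-like of shape (n_samples,), optional
            Per-point membership budgets ``w_k`` in [0, 1]; defaults to all
            ones (standard fuzzy c-means).
        """
        cfg = CFCMConfig(m=self.m, max_iter=self.max_iter, tol=self.tol)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN or infinite values")
        N = X.shape[0]
        if context_weights is None:
            w = np.ones(N)
        else:
            w = np.asarray(context_weights, dtype=float).ravel()
            if w.shape != (N,):
                raise ValueError("context_weights must have one entry per sample")
            if np.any(w < 0) or np.any(w > 1) or not np.all(np.isfinite(w)):
                raise ValueError("context_weights must lie in [0, 1]")
        n_pos = int(np.count_nonzero(w > 0))
        if n_pos < self.n_clusters:
            raise ValueError(
                f"only {n_pos} points have positive context membership but "
                f"{self.n_clusters} clusters were requested"
            )

        rng = np.random.default_rng(self.random_state)
        U = _init_partition(rng, self.n_clusters, w)
        V = _update_prototypes(X, U, X[:self.n_clusters].copy(), cfg.m)
        trace = []
        n_iter = 0
        for n_iter in range(1, cfg.max_iter + 1):
            U_new = _update_partition(X, V, w, cfg.m)
            trace.append(cfcm_objective(X, U_new, V, cfg.m))
            delta = float(np.max(np.abs(U_new - U)))
            U = U_new
            V = _update_prototypes(X, U, V, cfg.m)
            if delta < cfg.tol:
                break

        self.context_weights_ = w
        self.membership_ = U
        self.cluster_centers_ = V
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.labels_ = np.argmax(U, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def objective(self, X) -> float:
        check_is_fitted(self, "cluster_centers_")
        return cfcm_objective(X, self.membership_, self.cluster_centers_, self.m)


def cfcm_fit(X, w_l, c: int, config: CFCMConfig | None = None,
             context_index: int = -1) -> CFCMResult:
    """Fit CFCM within one context (thin wrapper over the estimator).

    Parameters
    ----------
    X : array-like of shape (N, d)
    w_l : array-like of shape (N,)
        Membership of each point in the ``l``-th context.
    c : int
        Number of clusters within this context.
    config : CFCMConfig, optional
    context_index : int
        Recorded on the result for bookkeeping.
    """
    cfg = config if config is not None else CFCMConfig()
    est = ContextFuzzyCMeans(
        n_clusters=c, m=cfg.m, max_iter=cfg.max_iter, tol=cfg.tol,
        random_state=cfg.seed,
    ).fit(X, context_weights=w_l)
    return CFCMResult(
        U=est.membership_,
        V=est.cluster_centers_,
        Q_trace=est.objective_trace_,
        context_index=context_index,
    )
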