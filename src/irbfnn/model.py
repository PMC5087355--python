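"""The incremental RBF network regressor and its evaluation protocol.

The model is built in four stages on min-max normalised data:

1. an ordinary least-squares linear backbone producing the global output z;
2. triangular linguistic contexts over the training residuals e = y - z,
   with context-based fuzzy c-means run inside each context to place
   c x p cluster prototypes;
3. a Gaussian RBF hidden layer on those prototypes whose output weights are
   solved against the residuals in one least-squares pass;
4. the additive prediction Y = z + E, de-normalised back to target units.

Because the zero-weight solution is always feasible in the least-squares
step, the model's training RMSE can never exceed that of its own linear
backbone.

The evaluation protocol mirrors the repeated-random-subsampling study
design: min-max normalisation to [0, 1], a random ~60/40 train/test split
repeated ``n_repeats`` times, and a grid search over the number of
contexts p and clusters per context c scored by mean test RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import ShuffleSplit
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .cfcm import CFCMConfig, CFCMResult, cfcm_fit
from .contexts import ContextFamily, build_contexts
from .rbf import RBFLayer, activations, estimate_widths, fit_output_weights, rbf_predict

__all__ = [
    "LinearModel",
    "IncrementalRBFRegressor",
    "EvaluationReport",
    "fit_linear",
    "fit_incremental",
    "predict",
    "rmse",
    "evaluate_grid",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# min-max normalisation (wrapped sklearn scaler with strict validation)

def minmax_fit(columns) -> MinMaxScaler:
    """Fit a [0, 1] min-max scaler; constant columns are rejected."""
    arr = np.asarray(columns, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot fit a scaler on non-finite data")
    spans = arr.max(axis=0) - arr.min(axis=0)
    if np.any(spans <= 0):
        bad = int(np.flatnonzero(spans <= 0)[0])
        raise ValueError(f"column {bad} is constant; min-max scaling is undefined")
    return MinMaxScaler().fit(arr)


def minmax_apply(scaler: MinMaxScaler, columns) -> np.ndarray:
    """Affine map onto the training [0, 1] box; out-of-range values are not
    clipped (test values may fall outside [0, 1])."""
    arr = np.asarray(columns, dtype=float)
    squeeze = arr.ndim == 1
    out = scaler.transform(arr[:, None] if squeeze else arr)
    return out.ravel() if squeeze else out


def minmax_invert(scaler: MinMaxScaler, columns) -> np.ndarray:
    arr = np.asarray(columns, dtype=float)
    squeeze = arr.ndim == 1
    out = scaler.inverse_transform(arr[:, None] if squeeze else arr)
    return out.ravel() if squeeze else out


# ---------------------------------------------------------------------------
# linear backbone

@dataclass(frozen=True)
class LinearModel:
    """OLS backbone: z(x) = intercept + coefficients . x."""

    coefficients: np.ndarray = field(repr=False)
    intercept: float = 0.0

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float).ravel()
        if not (np.all(np.isfinite(coef)) and np.isfinite(self.intercept)):
            raise ValueError("linear model parameters must be finite")
        object.__setattr__(self, "coefficients", coef)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept


def fit_linear(X, y) -> LinearModel:
    """Ordinary least squares with intercept.

    Requires N > d + 1 and a full-rank design (after adding the intercept
    column); residuals of the fit have zero mean.
    """
    X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    n, d = X.shape
    if n <= d + 1:
        raise ValueError(f"need more than {d + 1} samples to fit {d} slopes "
                         f"plus an intercept, got {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < d + 1:
        raise ValueError("design matrix is rank-deficient after adding the "
                         "intercept; remove collinear features")
    lr = LinearRegression().fit(X, y)
    return LinearModel(coefficients=lr.coef_, intercept=float(lr.intercept_))


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error, sqrt(sum (y_k - y'_k)^2 / N)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("cannot compute RMSE of empty vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    return float(np.sqrt(mean_squared_error(y_true, y_pred)))


# ---------------------------------------------------------------------------
# the estimator

class IncrementalRBFRegressor(RegressorMixin, BaseEstimator):
    """Linear regression refined by a context-clustered Gaussian RBF layer.

    Parameters
    ----------
    n_contexts : int, default=3
        Number p of triangular linguistic contexts on the residual axis.
    n_clusters : int, default=3
        Number c of CFCM clusters within each context; the hidden layer has
        exactly ``c * p`` units.
    m : float, default=2.0
        CFCM fuzzification exponent (> 1).
    ridge : float, default=0.0
        Optional Tikhonov term on the RBF output weights.  0 keeps the
        plain one-pass least-squares solve; a tiny value (e.g. 1e-8) guards
        against the ill-conditioning that large (p, c) grids can produce.
    max_iter, tol : CFCM iteration controls.
    normalized_rbf : bool, default=False
        If True, hidden activations are normalised to sum to one per sample
        before the output combination.
    normalize_target : bool, default=True
        Min-max scale the target as well as the features; predictions are
        always returned in original target units.
    random_state : int or None
        Seed for the CFCM initialisations.

    Attributes
    ----------
    linear_ : LinearModel
        The global backbone (normalised space).
    contexts_ : ContextFamily
        Triangular contexts built on the training residuals.
    cfcm_results_ : list of CFCMResult
        Per-context clustering outcomes.
    layer_ : RBFLayer
        Fitted hidden layer (centers, widths, output weights).
    n_hidden_ : int
        ``n_clusters * n_contexts``.
    feature_scaler_, target_scaler_ : fitted min-max scalers
        (``target_scaler_`` is None when ``normalize_target=False``).
    """

    def __init__(
        self,
        n_contexts: int = 3,
        n_clusters: int = 3,
        *,
        m: float = 2.0,
        ridge: float = 0.0,
        max_iter: int = 100,
        tol: float = 1e-5,
        normalized_rbf: bool = False,
        normalize_target: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.n_contexts = n_contexts
        self.n_clusters = n_clusters
        self.m = m
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self.normalized_rbf = normalized_rbf
        self.normalize_target = normalize_target
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "IncrementalRBFRegressor":
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        p, c = int(self.n_contexts), int(self.n_clusters)
        if p < 2:
            raise ValueError("n_contexts must be >= 2")
        if c < 1:
            raise ValueError("n_clusters must be >= 1")
        cfg = CFCMConfig(m=self.m, max_iter=self.max_iter, tol=self.tol)

        self.feature_scaler_ = minmax_fit(X)
        Xn = minmax_apply(self.feature_scaler_, X)
        if self.normalize_target:
            self.target_scaler_ = minmax_fit(y)
            yn = minmax_apply(self.target_scaler_, y)
        else:
            self.target_scaler_ = None
            yn = y.copy()

        self.linear_ = fit_linear(Xn, yn)
        z = self.linear_.predict(Xn)
        resid = yn - z
        self.contexts_ = build_contexts(resid, p)
        W = self.contexts_.membership(resid)  # (N, p)

        seeds = np.random.default_rng(self.random_state).integers(2**31, size=p)
        results: list[CFCMResult] = []
        for l in range(p):
            w_l = W[:, l]
            n_pos = int(np.count_nonzero(w_l > 0))
            if n_pos < c:
                raise ValueError(
                    f"context {l + 1} of {p} covers only {n_pos} residuals "
                    f"with positive membership but c={c} clusters were "
                    f"requested; reduce p or c"
                )
            cfg_l = CFCMConfig(m=cfg.m, max_iter=cfg.max_iter, tol=cfg.tol,
                               seed=int(seeds[l]))
            results.append(cfcm_fit(Xn, w_l, c, cfg_l, context_index=l))
        self.cfcm_results_ = results

        centers = np.vstack([r.V for r in results])
        widths = estimate_widths(Xn, results, m=self.m)
        layer = RBFLayer(centers=centers, widths=widths,
                         normalized=self.normalized_rbf)
        Phi = activations(Xn, layer)
        layer.weights = fit_output_weights(Phi, resid, ridge=self.ridge)
        self.layer_ = layer
        self.n_hidden_ = layer.n_units
        self.n_features_in_ = X.shape[1]

        fitted_n = z + Phi @ layer.weights
        self.fitted_values_ = self._denorm_target(fitted_n)
        self.train_rmse_ = rmse(y, self.fitted_values_)
        self.train_rmse_linear_ = rmse(y, self._denorm_target(z))
        logger.info(
            "fitted incremental model: p=%d, c=%d, %d hidden units, "
            "train RMSE %.4f (linear backbone %.4f)",
            p, c, self.n_hidden_, self.train_rmse_, self.train_rmse_linear_,
        )
        return self

    def _denorm_target(self, yn: np.ndarray) -> np.ndarray:
        if self.target_scaler_ is None:
            return yn
        return minmax_invert(self.target_scaler_, yn)

    # -- prediction --------------------------------------------------------

    def _check_predict_input(self, X) -> np.ndarray:
        check_is_fitted(self, "layer_")
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features but the model was fitted on "
                f"{self.n_features_in_}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """Additive prediction Y = z + E, returned in original target units."""
        X = self._check_predict_input(X)
        Xn = minmax_apply(self.feature_scaler_, X)
        out = self.linear_.predict(Xn) + rbf_predict(Xn, self.layer_)
        return self._denorm_target(out)

    def predict_linear(self, X) -> np.ndarray:
        """Backbone-only prediction z (original target units)."""
        X = self._check_predict_input(X)
        Xn = minmax_apply(self.feature_scaler_, X)
        return self._denorm_target(self.linear_.predict(Xn))


# ---------------------------------------------------------------------------
# functional wrappers

def fit_incremental(X, y, p: int, c: int,
                    config: CFCMConfig | None = None,
                    **kwargs) -> IncrementalRBFRegressor:
    """Fit the full four-stage pipeline (thin wrapper over the estimator)."""
    cfg = config if config is not None else CFCMConfig()
    return IncrementalRBFRegressor(
        n_contexts=p, n_clusters=c, m=cfg.m, max_iter=cfg.max_iter,
        tol=cfg.tol, random_state=cfg.seed, **kwargs,
    ).fit(X, y)


def predict(model: IncrementalRBFRegressor, X) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# repeated-split grid evaluation

@dataclass
class GridCell:
    """Per-(p, c) outcome over the repeated splits."""

    p: int
    c: int
    train_rmses: list[float] = field(default_factory=list)
    test_rmses: list[float] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.failures)

    @property
    def mean_train_rmse(self) -> float:
        ok = [v for v in self.train_rmses if np.isfinite(v)]
        return float(np.mean(ok)) if ok else float("nan")

    @property
    def mean_test_rmse(self) -> float:
        ok = [v for v in self.test_rmses if np.isfinite(v)]
        return float(np.mean(ok)) if ok else float("nan")


@dataclass
class EvaluationReport:
    """Grid-search outcome: one cell per (p, c), averaged over repeats."""

    p_values: list[int]
    c_values: list[int]
    cells: dict[tuple[int, int], GridCell] = field(repr=False)
    n_repeats: int = 10
    split_fraction: float = 0.6
    seed: int | None = None

    @property
    def best(self) -> tuple[int, int]:
        """(p, c) with the smallest mean test RMSE among successful cells."""
        ok = {pc: cell.mean_test_rmse for pc, cell in self.cells.items()
              if np.isfinite(cell.mean_test_rmse)}
        if not ok:
            raise ValueError("every grid cell failed; no best configuration")
        return min(ok, key=ok.get)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"p": cell.p, "c": cell.c,
             "mean_train_rmse": cell.mean_train_rmse,
             "mean_test_rmse": cell.mean_test_rmse,
             "n_failed": cell.n_failed}
            for cell in self.cells.values()
        ]
        return pd.DataFrame(rows).sort_values(["p", "c"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate_grid(X, y, p_range=range(3, 7), c_range=range(2, 7),
                  n_repeats: int = 10, split_fraction: float = 0.6,
                  seed: int | None = None, **model_kwargs) -> EvaluationReport:
    """Repeated random-split grid search over (contexts p, clusters c).

    For each repeat a single random split (train fraction ``split_fraction``,
    train size floored) is shared across all grid cells; each cell fits the
    incremental model on the training part and reports train and test RMSE
    in original target units.  Cells whose fit fails (e.g. an
    under-populated context) are recorded as failed with the reason, never
    silently skipped; their summary statistics are NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p_values, c_values = list(p_range), list(c_range)
    if not p_values or not c_values:
        raise ValueError("p_range and c_range must be non-empty")
    n = X.shape[0]
    n_train = int(np.floor(split_fraction * n))
    largest = max(p_values) * max(c_values)
    if n_train < largest:
        raise ValueError(
            f"training split of {n_train} samples is smaller than the "
            f"largest hidden layer ({largest} units); enlarge the dataset "
            f"or shrink the grid"
        )
    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(2**31))
    fit_seeds = rng.integers(2**31, size=n_repeats)
    splitter = ShuffleSplit(n_splits=n_repeats, train_size=split_fraction,
                            random_state=split_seed)
    cells = {(p, c): GridCell(p=p, c=c) for p in p_values for c in c_values}
    for rep, (tr, te) in enumerate(splitter.split(X)):
        X_tr, X_te, y_tr, y_te = X[tr], X[te], y[tr], y[te]
        for (p, c), cell in cells.items():
            try:
                est = IncrementalRBFRegressor(
                    n_contexts=p, n_clusters=c,
                    random_state=int(fit_seeds[rep]), **model_kwargs,
                ).fit(X_tr, y_tr)
            except ValueError as exc:
                logger.info("grid cell (p=%d, c=%d) repeat %d failed: %s",
                            p, c, rep, exc)
                cell.train_rmses.append(float("nan"))
                cell.test_rmses.append(float("nan"))
                cell.failures.append(f"repeat {rep}: {exc}")
                continue
            cell.train_rmses.append(rmse(y_tr, est.predict(X_tr)))
            cell.test_rmses.append(rmse(y_te, est.predict(X_te)))
    return EvaluationReport(p_values=p_values, c_values=c_values, cells=cells,
                            n_repeats=n_repeats, split_fraction=split_fraction,
                            seed=seed)
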