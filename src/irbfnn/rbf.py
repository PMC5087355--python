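"""Gaussian radial-basis hidden layer with one-pass least-squares weights.

The hidden units are seeded by the CFCM prototypes (``n = c x p`` units for
``c`` clusters in each of ``p`` contexts).  Unit ``i`` computes the
receptive field ``phi_i(x) = exp(-||x - v_i||^2 / (2 sigma_i^2))`` and the
layer output is the weighted sum ``E(x) = sum_i g_i phi_i(x)``.  The output
weights ``g`` are obtained in a single least-squares solve against the
linear model's residuals — no backpropagation, and centres/widths stay
fixed once placed.

Widths are not part of the clustering itself; here ``sigma_i`` is the
membership-weighted RMS distance of the data to centre ``i``, with the mean
pairwise distance between centres as a fallback for degenerate (singleton
or empty) clusters, so every width is strictly positive and in data units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .cfcm import CFCMResult

__all__ = [
    "RBFLayer",
    "estimate_widths",
    "activations",
    "fit_output_weights",
    "rbf_predict",
]

_WIDTH_EPS = 1e-6


@dataclass
class RBFLayer:
    """A fitted Gaussian RBF hidden layer.

    Attributes
    ----------
    centers : ndarray of shape (n, d)
        Hidden-unit centres (CFCM prototypes, feature units).
    widths : ndarray of shape (n,)
        Strictly positive Gaussian widths (feature units).
    weights : ndarray of shape (n,) or None
        Output weights ``g_i`` (target units); None until fitted.
    normalized : bool
        If True, activations are divided by their row sum (normalised-RBF
        variant); default False uses the plain weighted sum.
    """

    centers: np.ndarray = field(repr=False)
    widths: np.ndarray = field(repr=False)
    weights: np.ndarray | None = field(default=None, repr=False)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float).ravel()
        if self.centers.ndim != 2:
            raise ValueError("centers must be a 2-D array")
        if self.widths.shape[0] != self.centers.shape[0]:
            raise ValueError("one width per center required")
        if not np.all(self.widths > 0):
            raise ValueError("all widths must be strictly positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.shape[0] != self.centers.shape[0]:
                raise ValueError("one weight per center required")

    @property
    def n_units(self) -> int:
        return int(self.centers.shape[0])


def estimate_widths(X, results: Sequence[CFCMResult] | np.ndarray,
                    m: float = 2.0, centers=None) -> np.ndarray:
    """Membership-weighted RMS widths for the stacked hidden units.

    sigma_i = sqrt( sum_k u_ik^m ||x_k - v_i||^2 / sum_k u_ik^m )

    Any width below 1e-6, or undefined because a unit's memberships are all
    zero, falls back to the mean pairwise distance between all centres.

    Parameters
    ----------
    X : array-like of shape (N, d)
    results : sequence of CFCMResult, or membership matrix of shape (n, N)
        Per-context CFCM outcomes (stacked in order), or a pre-stacked
        membership matrix (then ``centers`` must be given).
    m : float
        Fuzzification exponent used for the weighting.
    centers : array-like of shape (n, d), optional
        Required when ``results`` is a raw membership matrix.

    Raises
    ------
    ValueError
        If the data carry a single distinct point (no spatial scale exists).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 data points to estimate widths")
    if np.all(X == X[0]):
        raise ValueError(
            "all data points are identical; no spatial scale is definable"
        )
    if centers is None:
        U = np.vstack([r.U for r in results])
        V = np.vstack([r.V for r in results])
    else:
        U = np.asarray(results, dtype=float)
        V = np.asarray(centers, dtype=float)
    d2 = cdist(V, X, metric="sqeuclidean")  # (n, N)
    Um = U**m
    denom = Um.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.sqrt((Um * d2).sum(axis=1) / denom)
    bad = ~np.isfinite(sigma) | (sigma < _WIDTH_EPS)
    if bad.any():
        if V.shape[0] >= 2:
            fallback = float(pdist(V).mean())
        else:
            fallback = 0.0
        if fallback < _WIDTH_EPS:
            # centres coincide too; fall back to the global data spread
            fallback = float(pdist(X).mean())
        if fallback < _WIDTH_EPS:
            raise ValueError("cannot define a positive width: data and "
                             "centres carry no spatial scale")
        sigma[bad] = fallback
    return sigma


def activations(X, layer: RBFLayer) -> np.ndarray:
    """Receptive-field matrix Phi with Phi[k, i] = exp(-||x_k - v_i||^2 / 2 sigma_i^2)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] != layer.centers.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} features but layer centers have "
            f"{layer.centers.shape[1]}"
        )
    d2 = cdist(X, layer.centers, metric="sqeuclidean")
    Phi = np.exp(-d2 / (2.0 * layer.widths**2))
    if layer.normalized:
        Phi = Phi / Phi.sum(axis=1, keepdims=True)
    return Phi


def fit_output_weights(Phi, e, ridge: float = 0.0) -> np.ndarray:
    """One-pass least-squares output weights.

    Solves ``argmin_g ||e - Phi g||^2 + ridge ||g||^2``.  With ``ridge=0``
    a rank-revealing solve returns the minimum-norm solution for
    rank-deficient Phi.
    """
    Phi = np.asarray(Phi, dtype=float)
    e = np.asarray(e, dtype=float).ravel()
    if Phi.ndim != 2 or Phi.shape[0] != e.shape[0]:
        raise ValueError("Phi rows must match the residual vector length")
    if not (np.all(np.isfinite(Phi)) and np.all(np.isfinite(e))):
        raise ValueError("non-finite entries in the least-squares system")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge == 0.0:
        g, *_ = np.linalg.lstsq(Phi, e, rcond=None)
        return g
    n = Phi.shape[1]
    A = Phi.T @ Phi + ridge * np.eye(n)
    return np.linalg.solve(A, Phi.T @ e)


def rbf_predict(X, layer: RBFLayer) -> np.ndarray:
    """Nonlinear correction E(x) = Phi(x) @ g for a fully fitted layer."""
    if layer.weights is None:
        raise ValueError("layer output weights are not fitted")
    return activations(X, layer) @ layer.weights
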