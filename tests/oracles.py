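"""Independent brute-force oracles used only by the test suite.

Deliberately written with explicit Python loops and textbook formulas so
they share no code path with the package implementation.
"""

import numpy as np


def standard_fcm(X, c, m=2.0, max_iter=100, tol=1e-5, seed=None):
    """Plain-loop standard fuzzy c-means.

    Initialisation mirrors the package's convention (uniform random
    partition matrix with unit column sums drawn from default_rng(seed))
    so that, run on the same data, both algorithms follow the same
    trajectory; every update below is computed with explicit loops.
    Returns (U, V) with U of shape (c, N).
    """
    X = np.asarray(X, dtype=float)
    N, d = X.shape
    rng = np.random.default_rng(seed)
    U = rng.random((c, N))
    for k in range(N):
        U[:, k] = U[:, k] / sum(U[i, k] for i in range(c))
    V = np.zeros((c, d))
    for _ in range(max_iter):
        for i in range(c):
            num = np.zeros(d)
            den = 0.0
            for k in range(N):
                num += U[i, k] ** m * X[k]
                den += U[i, k] ** m
            V[i] = num / den
        U_new = np.zeros_like(U)
        for k in range(N):
            dists = [np.sqrt(((X[k] - V[j]) ** 2).sum()) for j in range(c)]
            if min(dists) == 0.0:
                hits = [j for j in range(c) if dists[j] == 0.0]
                for j in hits:
                    U_new[j, k] = 1.0 / len(hits)
            else:
                for i in range(c):
                    s = sum((dists[i] / dists[j]) ** (2.0 / (m - 1.0))
                            for j in range(c))
                    U_new[i, k] = 1.0 / s
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break
    # final prototype refresh so V corresponds to the returned partition
    for i in range(c):
        num = np.zeros(d)
        den = 0.0
        for k in range(N):
            num += U[i, k] ** m * X[k]
            den += U[i, k] ** m
        V[i] = num / den
    return U, V


def normal_equations_lstsq(A, b):
    """Least squares via explicit normal equations (A'A)^-1 A'b."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.linalg.solve(A.T @ A, A.T @ b)


def loop_rmse(y, yhat):
    """Elementwise RMSE with an explicit accumulation loop."""
    total = 0.0
    for a, b in zip(y, yhat):
        total += (a - b) ** 2
    return (total / len(y)) ** 0.5
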