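"""Triangular linguistic contexts over the residual (output) space.

A context family is a half-overlap triangular fuzzy partition of the
interval spanned by the linear model's training residuals.  Peaks are
equally spaced over ``[e_min, e_max]`` (both endpoints included), interior
contexts are full triangles reaching zero at the neighbouring peaks, and
the first/last contexts are half-triangles clipped at the domain edges.
By construction the memberships form a partition of unity on the domain;
residuals outside the domain are clamped to the nearest edge so that
membership evaluation is a total function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContextFamily", "build_contexts", "context_membership"]


@dataclass(frozen=True)
class ContextFamily:
    """A family of ``p`` triangular membership functions on the residual axis.

    Attributes
    ----------
    peaks : ndarray of shape (p,)
        Strictly increasing, equally spaced peak positions; ``peaks[0]`` is
        the domain minimum and ``peaks[-1]`` the domain maximum.  Context
        ``l`` has membership 1 at ``peaks[l]`` and 0 at every other peak.
    """

    peaks: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.ndim != 1 or peaks.size < 2:
            raise ValueError("a context family needs at least 2 peaks")
        if not np.all(np.isfinite(peaks)):
            raise ValueError("context peaks must be finite")
        if not np.all(np.diff(peaks) > 0):
            raise ValueError("context peaks must be strictly increasing")
        object.__setattr__(self, "peaks", peaks)

    @property
    def n_contexts(self) -> int:
        return int(self.peaks.size)

    @property
    def domain(self) -> tuple[float, float]:
        """``(e_min, e_max)`` of the residuals the family was built on."""
        return float(self.peaks[0]), float(self.peaks[-1])

    @property
    def supports(self) -> list[tuple[float, float, float]]:
        """Per-context ``(left, peak, right)`` support triples."""
        t = self.peaks
        out = []
        for l in range(t.size):
            left = t[l - 1] if l > 0 else t[0]
            right = t[l + 1] if l < t.size - 1 else t[-1]
            out.append((float(left), float(t[l]), float(right)))
        return out

    def membership(self, e) -> np.ndarray:
        """Evaluate all context memberships at residual value(s) ``e``.

        Parameters
        ----------
        e : float or array-like of shape (N,)
            Residual values; values outside the domain are clamped to the
            nearest domain edge before evaluation.

        Returns
        -------
        ndarray of shape (p,) or (N, p)
            Memberships ``w_l(e)`` in [0, 1]; rows sum to 1.
        """
        e_arr = np.asarray(e, dtype=float)
        scalar = e_arr.ndim == 0
        e_arr = np.atleast_1d(e_arr)
        if not np.all(np.isfinite(e_arr)):
            raise ValueError("residual values must be finite")
        t = self.peaks
        e_arr = np.clip(e_arr, t[0], t[-1])
        p = t.size
        W = np.empty((e_arr.size, p))
        # np.interp extends flat beyond the node range, which yields exactly
        # the clipped half-triangles at the two domain edges.
        W[:, 0] = np.interp(e_arr, t[:2], [1.0, 0.0])
        for l in range(1, p - 1):
            W[:, l] = np.interp(e_arr, t[l - 1 : l + 2], [0.0, 1.0, 0.0])
        W[:, -1] = np.interp(e_arr, t[-2:], [0.0, 1.0])
        return W[0] if scalar else W


def build_contexts(residuals, p: int) -> ContextFamily:
    """Build ``p`` equally spaced triangular contexts spanning the residuals.

    Peaks sit at ``e_min + (l-1)(e_max - e_min)/(p-1)`` for ``l = 1..p``,
    i.e. evenly over the residual range with both endpoints included.

    Raises
    ------
    ValueError
        If ``p < 2``, the residuals are empty/non-finite, or all residuals
        are identical (degenerate domain: no range to partition).
    """
    if p < 2:
        raise ValueError(f"need at least 2 contexts, got p={p}")
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("residuals are empty")
    if not np.all(np.isfinite(e)):
        raise ValueError("residuals must be finite")
    e_min, e_max = float(e.min()), float(e.max())
    if e_max <= e_min:
        raise ValueError(
            "all residuals are identical; cannot build contexts over a "
            "degenerate (zero-width) domain"
        )
    return ContextFamily(np.linspace(e_min, e_max, p))


def context_membership(family: ContextFamily, e) -> np.ndarray:
    """Functional alias for :meth:`ContextFamily.membership`."""
    return family.membership(e)
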