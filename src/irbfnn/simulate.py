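"""Seeded synthetic datasets with the structure the incremental model assumes.

The generator emulates submaximal-exercise energy-expenditure data: a
dominant linear trend of EE (kcal/min) on heart rate HR (bpm) and movement
index MI (dimensionless accelerometer magnitude), plus localised Gaussian
bumps — regions of the input space where the true relation departs from
the global linear backbone — and additive Gaussian measurement noise.
Gaussian bumps are used because they are exactly representable by the RBF
hidden layer, which makes centre recovery a sharp test of the pipeline.

Default ranges (HR in [60, 190] bpm, MI in [0, 6]) and coefficients are
conventions chosen to resemble walking-to-running intensities; they are
not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset

__all__ = ["SimulationSpec", "simulate_ee_dataset", "simulate_piecewise_nonlinear"]

#: (center_HR, center_MI, amplitude kcal/min, width) of the default bumps:
#: an extra cost near the run transition and a small economy dip at easy walking.
_DEFAULT_BUMPS: tuple[tuple[float, float, float, float], ...] = (
    (150.0, 4.5, 1.5, 12.0),
    (95.0, 1.5, -1.0, 10.0),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the linear-plus-bumps EE generator.

    Attributes
    ----------
    n : int
        Sample count (252 mirrors a single treadmill session's pair count).
    linear_coefs : (beta0, beta_HR, beta_MI)
        Intercept and slopes of the linear backbone, kcal/min per unit.
    bumps : tuple of (center_HR, center_MI, amplitude, width)
        Isotropic Gaussian deviations added to the linear trend.
    noise_sd : float
        SD of additive Gaussian noise on EE, kcal/min.
    hr_range, mi_range : (low, high)
        Uniform sampling intervals for the two inputs.
    seed : int or None
        Seed; the output is a pure function of the spec.
    """

    n: int = 252
    linear_coefs: tuple[float, float, float] = (-3.0, 0.07, 0.6)
    bumps: tuple[tuple[float, float, float, float], ...] = _DEFAULT_BUMPS
    noise_sd: float = 0.2
    hr_range: tuple[float, float] = (60.0, 190.0)
    mi_range: tuple[float, float] = (0.0, 6.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lo, hi in (self.hr_range, self.mi_range):
            if not hi > lo:
                raise ValueError("sampling ranges must be non-degenerate")
        for bump in self.bumps:
            if len(bump) != 4:
                raise ValueError("each bump is (center_HR, center_MI, amplitude, width)")
            if bump[3] <= 0:
                raise ValueError("bump widths must be positive")


def _bump_surface(hr: np.ndarray, mi: np.ndarray,
                  bumps) -> np.ndarray:
    out = np.zeros_like(hr)
    for c_hr, c_mi, amp, width in bumps:
        d2 = (hr - c_hr) ** 2 + (mi - c_mi) ** 2
        out += amp * np.exp(-d2 / (2.0 * width**2))
    return out


def simulate_ee_dataset(spec: SimulationSpec = SimulationSpec()) -> Dataset:
    """Draw a seeded HR/MI/EE dataset from the linear-plus-bumps model.

    EE = b0 + b_HR*HR + b_MI*MI + sum_j amp_j exp(-[(HR-cHR_j)^2 +
    (MI-cMI_j)^2] / (2 width_j^2)) + Normal(0, noise_sd).

    Returns a :class:`Dataset` whose ``signal`` field holds the noiseless EE.
    """
    rng = np.random.default_rng(spec.seed)
    hr = rng.uniform(*spec.hr_range, size=spec.n)
    mi = rng.uniform(*spec.mi_range, size=spec.n)
    b0, b_hr, b_mi = spec.linear_coefs
    signal = b0 + b_hr * hr + b_mi * mi + _bump_surface(hr, mi, spec.bumps)
    ee = signal + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return Dataset(
        X=np.column_stack([hr, mi]), y=ee,
        feature_names=("hr", "mi"), target_name="ee", signal=signal,
    )


#: Fixed benchmark surface on [0,1]^2: a plane plus three sign-alternating
#: Gaussian bumps of width 0.1.
_PW_BUMPS: tuple[tuple[float, float, float, float], ...] = (
    (0.25, 0.25, 0.8, 0.1),
    (0.75, 0.75, -0.8, 0.1),
    (0.75, 0.25, 0.6, 0.1),
)


def simulate_piecewise_nonlinear(n: int, seed: int | None = None, *,
                                 noise_sd: float = 0.0,
                                 include_bumps: bool = True) -> Dataset:
    """Generic 2-input benchmark: f(x1,x2) = 1 + 2*x1 - x2 plus (optionally)
    three sign-alternating Gaussian bumps of width 0.1, sampled at uniform
    random inputs on the unit square.

    Used for grid-search and recovery property tests; ``include_bumps=False``
    degenerates to the purely linear case.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(n, 2))
    signal = 1.0 + 2.0 * x[:, 0] - x[:, 1]
    if include_bumps:
        signal = signal + _bump_surface(x[:, 0], x[:, 1], _PW_BUMPS)
    y = signal + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    return Dataset(X=x, y=y, feature_names=("x1", "x2"), target_name="y",
                   signal=signal)
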