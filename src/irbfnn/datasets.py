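"""Lightweight tabular container shared by the simulator, IO and model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """An ``N x d`` feature matrix with a length-``N`` target vector.

    ``signal`` optionally carries the noiseless target (known only for
    simulated data) so recovery tests can compare against ground truth.
    """

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...] = ("hr", "mi")
    target_name: str = "ee"
    signal: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one feature name per column required")
        if self.signal is not None:
            self.signal = np.asarray(self.signal, dtype=float).ravel()
            if self.signal.shape != self.y.shape:
                raise ValueError("signal must match y in length")

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df[self.target_name] = self.y
        if self.signal is not None:
            df["signal"] = self.signal
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
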