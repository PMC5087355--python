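"""CSV dataset IO and JSON model persistence."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contexts import ContextFamily
from .datasets import Dataset
from .model import IncrementalRBFRegressor, LinearModel, minmax_fit
from .rbf import RBFLayer

__all__ = ["read_dataset", "write_dataset", "save_model", "load_model", "SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def read_dataset(path, feature_cols: Sequence[str], target_col: str) -> Dataset:
    """Load a tabular CSV into a Dataset.

    Rows containing any missing value in the used columns are dropped (the
    count is logged).  Missing columns, non-numeric cells and an empty
    result raise ValueError naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    wanted = list(feature_cols) + [target_col]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {missing}")
    sub = df[wanted]
    for col in wanted:
        coerced = pd.to_numeric(sub[col], errors="coerce")
        newly_bad = coerced.isna() & sub[col].notna()
        if newly_bad.any():
            raise ValueError(
                f"column '{col}' contains non-numeric value(s), e.g. "
                f"{sub[col][newly_bad].iloc[0]!r}"
            )
        sub = sub.assign(**{col: coerced})
    n_before = len(sub)
    sub = sub.dropna()
    dropped = n_before - len(sub)
    if dropped:
        logger.warning("dropped %d row(s) with missing values from %s",
                       dropped, path)
    if len(sub) == 0:
        raise ValueError(f"{path} has no usable rows after dropping missing values")
    return Dataset(
        X=sub[list(feature_cols)].to_numpy(float),
        y=sub[target_col].to_numpy(float),
        feature_names=tuple(feature_cols),
        target_name=target_col,
    )


def write_dataset(ds: Dataset, path) -> None:
    ds.to_csv(path)


def _scaler_state(scaler):
    if scaler is None:
        return None
    return {"data_min": scaler.data_min_.tolist(),
            "data_max": scaler.data_max_.tolist()}


def _scaler_restore(state):
    if state is None:
        return None
    mins = np.asarray(state["data_min"], dtype=float)
    maxs = np.asarray(state["data_max"], dtype=float)
    # re-fitting on the two extreme rows reproduces the scaler bit-exactly
    return minmax_fit(np.vstack([mins, maxs]))


def save_model(model: IncrementalRBFRegressor, path) -> None:
    """Serialise a fitted model to a single JSON document."""
    if not hasattr(model, "layer_"):
        raise ValueError("cannot save an unfitted model")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "feature_scaler": _scaler_state(model.feature_scaler_),
        "target_scaler": _scaler_state(model.target_scaler_),
        "linear": {
            "coefficients": model.linear_.coefficients.tolist(),
            "intercept": model.linear_.intercept,
        },
        "context_peaks": model.contexts_.peaks.tolist(),
        "layer": {
            "centers": model.layer_.centers.tolist(),
            "widths": model.layer_.widths.tolist(),
            "weights": model.layer_.weights.tolist(),
            "normalized": bool(model.layer_.normalized),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> IncrementalRBFRegressor:
    """Reconstruct a fitted model; predictions are bit-identical to the
    original on the same inputs."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path} is not valid model JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r}; this build "
            f"reads version {SCHEMA_VERSION}"
        )
    model = IncrementalRBFRegressor(**doc["params"])
    model.n_features_in_ = int(doc["n_features_in"])
    model.feature_scaler_ = _scaler_restore(doc["feature_scaler"])
    model.target_scaler_ = _scaler_restore(doc["target_scaler"])
    model.linear_ = LinearModel(
        coefficients=np.asarray(doc["linear"]["coefficients"], dtype=float),
        intercept=float(doc["linear"]["intercept"]),
    )
    model.contexts_ = ContextFamily(np.asarray(doc["context_peaks"], dtype=float))
    lay = doc["layer"]
    model.layer_ = RBFLayer(
        centers=np.asarray(lay["centers"], dtype=float),
        widths=np.asarray(lay["widths"], dtype=float),
        weights=np.asarray(lay["weights"], dtype=float),
        normalized=bool(lay["normalized"]),
    )
    model.n_hidden_ = model.layer_.n_units
    return model
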