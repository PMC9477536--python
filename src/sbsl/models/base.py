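"""Model containers and scoring.

A :class:`TrainedModel` bundles the model kind, its hyperparameters, the
fitted parameters, the feature names seen at fit time and (optionally) the
preprocessing statistics learned on the training set, so that prediction on
raw feature tables is deterministic and leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = ["Preprocessor", "TrainedModel", "predict_score", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class Preprocessor:
    """Train-set imputation (medians) and standardization (mean/sd) applied
    to the kept feature columns; fit on train data only."""

    feature_names: List[str]
    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from input: {missing}")
        arr = X[self.feature_names].to_numpy(dtype=float).copy()
        for j in range(arr.shape[1]):
            col = arr[:, j]
            col[~np.isfinite(col)] = self.medians[j]
        return (arr - self.means) / self.sds

    @classmethod
    def fit(cls, X: pd.DataFrame, min_nonconstant_frac: float = 0.05) -> "Preprocessor":
        """Learn imputation/standardization stats and drop features whose
        train vector is >= 95% a single value (missing counted toward the
        modal value)."""
        kept, med, mean, sd = [], [], [], []
        n = len(X)
        for c in X.columns:
            col = X[c].to_numpy(dtype=float)
            finite = col[np.isfinite(col)]
            if finite.size == 0:
                continue
            vals, counts = np.unique(finite, return_counts=True)
            modal = counts.max() + (n - finite.size)
            if modal / n > 1.0 - min_nonconstant_frac:
                continue
            m = float(np.median(finite))
            filled = np.where(np.isfinite(col), col, m)
            mu = float(filled.mean())
            s = float(filled.std(ddof=0))
            if s == 0.0:
                continue
            kept.append(c)
            med.append(m)
            mean.append(mu)
            sd.append(s)
        if not kept:
            raise ValueError("all features filtered out")
        return cls(kept, np.array(med), np.array(mean), np.array(sd))


@dataclass
class TrainedModel:
    kind: str  # elastic_net | l0l2 | muvr_rf | rrf
    hyperparameters: Dict[str, Any]
    feature_names: List[str]
    selected_features: List[str]
    params: Dict[str, Any]
    seed: int
    preprocess: Optional[Preprocessor] = None
    meta: Dict[str, Any] = field(default_factory=dict)


def predict_score(model: TrainedModel, X) -> np.ndarray:
    """Scores in [0, 1]; logistic probabilities for linear models, mean leaf
    positive fraction for forests. Deterministic given the model.

    ``X`` may be a raw feature DataFrame (the stored preprocessing is
    applied) or an already-processed array over ``model.feature_names``.
    """
    if isinstance(X, pd.DataFrame):
        if model.preprocess is not None:
            arr = model.preprocess.transform(X)
        else:
            missing = [c for c in model.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"feature columns missing from input: {missing}")
            arr = X[model.feature_names].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} columns, got {arr.shape[1]}"
            )

    if model.kind in ("elastic_net", "l0l2"):
        coef = np.asarray(model.params["coef"], dtype=float)
        intercept = float(model.params["intercept"])
        return sigmoid(arr @ coef + intercept)
    if model.kind == "rrf":
        from ._forest_kernels import forest_predict

        p = model.params
        return forest_predict(
            np.ascontiguousarray(arr), p["feat"], p["thr"], p["left"], p["right"], p["value"]
        )
    if model.kind == "muvr_rf":
        rf = model.params["forest"]
        cols = [model.feature_names.index(f) for f in model.selected_features]
        return rf.predict_proba(arr[:, cols])[:, 1]
    raise ValueError(f"unknown model kind {model.kind!r}")
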