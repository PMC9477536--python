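"""Regularized random forests: penalized-gain RRF and MUVR-style
backward-elimination forests.

RRF grows its trees with a global used-feature set: a split on a feature new
to the forest has its Gini gain multiplied by ``coef_reg``; with
``coef_reg = 1`` the model is an ordinary random forest. MUVR wraps plain
random forests in repeated, nested cross-validation with geometric backward
feature elimination, and refits on the "mid" optimal feature count (the
rounded geometric mean of the smallest and largest optimal counts found
across folds and repetitions).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ..metrics import auroc
from ._forest_kernels import forest_predict, grow_forest
from .base import TrainedModel

__all__ = ["fit_rrf", "fit_muvr"]


def fit_rrf(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int = 5,
    coef_reg: float = 0.8,
    seed: int = 0,
    n_trees: int = 500,
    min_leaf: int = 5,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Penalized-gain random forest (seed-deterministic)."""
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.ascontiguousarray(np.asarray(y).astype(np.int64))
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    if not (0.0 < coef_reg <= 1.0):
        raise ValueError("coef_reg must lie in (0, 1]")
    p = X.shape[1]
    if mtry > p:
        raise ValueError(f"mtry {mtry} exceeds {p} features")
    feat, thr, left, right, value, used = grow_forest(
        X, y, int(n_trees), int(mtry), float(coef_reg), int(min_leaf), int(seed) % (2 ** 31)
    )
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    return TrainedModel(
        kind="rrf",
        hyperparameters={"mtry": int(mtry), "coefReg": float(coef_reg),
                         "n_trees": int(n_trees), "min_leaf": int(min_leaf)},
        feature_names=names,
        selected_features=[names[j] for j in np.flatnonzero(used)],
        params={"feat": feat, "thr": thr, "left": left, "right": right, "value": value},
        seed=seed,
        meta={"n": len(y), "pos_frac": float(y.mean())},
    )


def fit_muvr(
    X: np.ndarray,
    y: np.ndarray,
    n_rep: int = 5,
    n_outer: int = 10,
    var_ratio: float = 0.8,
    seed: int = 0,
    inner_trees: int = 100,
    final_trees: int = 500,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Random forest with repeated nested-CV backward feature elimination."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    if not (0.0 < var_ratio < 1.0):
        raise ValueError("var_ratio must lie in (0, 1) for the schedule to terminate")
    n, p = X.shape
    if n_outer > n:
        raise ValueError("more outer folds than samples")
    min_class = np.bincount(y).min()
    if n_outer > min_class:
        raise ValueError("more outer folds than minority-class samples")

    optima = []
    for rep in range(n_rep):
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed + 1000 * rep)
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            current = np.arange(p)
            perf = []  # (n_features, val auroc)
            while True:
                rf = RandomForestClassifier(
                    n_estimators=inner_trees, random_state=seed + 7 * rep + fold, n_jobs=1
                )
                rf.fit(X[np.ix_(tr, current)], y[tr])
                scores = rf.predict_proba(X[np.ix_(va, current)])[:, 1]
                perf.append((current.size, auroc(scores, y[va])))
                if current.size <= 1:
                    break
                keep = max(1, math.floor(var_ratio * current.size))
                if keep == current.size:
                    keep = current.size - 1
                order = np.argsort(-rf.feature_importances_)
                current = current[np.sort(order[:keep])]
            sizes = np.array([s for s, _ in perf])
            aucs = np.array([a for _, a in perf])
            # ties toward the smaller feature count
            best_auc = aucs.max()
            optima.append(int(sizes[aucs >= best_auc - 1e-12].min()))

    n_min, n_max = min(optima), max(optima)
    n_mid = int(round(math.sqrt(n_min * n_max)))
    n_mid = max(1, min(n_mid, p))

    ranking_rf = RandomForestClassifier(n_estimators=final_trees, random_state=seed, n_jobs=1)
    ranking_rf.fit(X, y)
    top = np.sort(np.argsort(-ranking_rf.feature_importances_)[:n_mid])
    final_rf = RandomForestClassifier(n_estimators=final_trees, random_state=seed, n_jobs=1)
    final_rf.fit(X[:, top], y)

    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    return TrainedModel(
        kind="muvr_rf",
        hyperparameters={"nRep": n_rep, "nOuter": n_outer, "varRatio": var_ratio,
                         "inner_trees": inner_trees, "final_trees": final_trees},
        feature_names=names,
        selected_features=[names[j] for j in top],
        params={"forest": final_rf},
        seed=seed,
        meta={"n": n, "pos_frac": float(y.mean()),
              "n_opt_min": n_min, "n_opt_mid": n_mid, "n_opt_max": n_max},
    )
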