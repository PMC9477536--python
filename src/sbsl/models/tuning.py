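"""Hyperparameter search: repeated stratified k-fold CV scored by AUROC.

The default protocol is 10-fold cross-validation with five repeats on the
training set only. Grid ties break toward stronger regularization (larger
lambda, smaller support, smaller mtry / coefReg) so that tuning is
reproducible under flat CV surfaces.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from ..metrics import auroc
from .base import TrainedModel, predict_score
from .forest import fit_muvr, fit_rrf
from .linear import fit_elastic_net, fit_l0l2_single, sigmoid

__all__ = ["cross_val_auroc", "tune", "default_grid", "fit_model"]


def cross_val_auroc(
    fit_fn: Callable,
    score_fn: Callable,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    return_se: bool = False,
):
    """Mean AUROC of fit_fn/score_fn over repeated stratified folds,
    optionally with its standard error across folds.

    Folds whose validation side is single-class are skipped.
    """
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    aucs = []
    for tr, va in cv.split(X, y):
        if np.unique(y[va]).size < 2:
            continue
        model = fit_fn(X[tr], y[tr], seed)
        aucs.append(auroc(score_fn(model, X[va]), y[va]))
    if not aucs:
        raise ValueError("no valid CV fold")
    mean = float(np.mean(aucs))
    if not return_se:
        return mean
    if len(aucs) > 1:
        # Nadeau-Bengio variance correction: fold scores share training data,
        # so the naive sd/sqrt(J) badly understates the CV mean's variance
        rho = 1.0 / (folds - 1) if folds > 1 else 1.0
        se = float(np.std(aucs, ddof=1) * np.sqrt(1.0 / len(aucs) + rho))
    else:
        se = 0.0
    return mean, se


def default_grid(kind: str) -> List[Dict]:
    """Desk-scale grids covering the declared search spaces
    (lambda, alpha in [0,1]; mtry in [4,8]; coefReg in [0.5,1])."""
    if kind == "elastic_net":
        return [
            {"alpha": a, "lam": l}
            for a in (0.1, 0.5, 1.0)
            for l in (1e-3, 1e-2, 1e-1)
        ]
    if kind == "l0l2":
        return [
            {"k": k, "gamma": g}
            for k in (1, 2, 4, 8, 16)
            for g in (1e-4, 1e-2)
        ]
    if kind == "rrf":
        return [
            {"mtry": m, "coef_reg": c}
            for m in (4, 8)
            for c in (0.5, 1.0)
        ]
    if kind == "muvr_rf":
        return [{}]  # MUVR tunes itself through nested CV
    raise ValueError(f"unknown model kind {kind!r}")


def _regularization_strength(kind: str, point: Dict) -> tuple:
    """Sort key: stronger regularization first."""
    if kind == "elastic_net":
        return (-point["lam"], -point["alpha"])
    if kind == "l0l2":
        return (point["k"], -point["gamma"])
    if kind == "rrf":
        return (point["coef_reg"], point["mtry"])
    return (0,)


def _single_fit(kind: str, X, y, point: Dict, seed: int, fit_kwargs: Dict):
    if kind == "elastic_net":
        return fit_elastic_net(X, y, alpha=point["alpha"], lam=point["lam"], seed=seed)
    if kind == "l0l2":
        coef, b0 = fit_l0l2_single(X, y, point["k"], point["gamma"])
        return ("_l0l2", coef, b0)
    if kind == "rrf":
        return fit_rrf(X, y, mtry=point["mtry"], coef_reg=point["coef_reg"], seed=seed,
                       n_trees=fit_kwargs.get("cv_trees", 50))
    raise ValueError(f"unknown model kind {kind!r}")


def _single_score(model, X):
    if isinstance(model, tuple) and model[0] == "_l0l2":
        _, coef, b0 = model
        return sigmoid(X @ coef + b0)
    return predict_score(model, X)


def tune(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: Optional[Sequence[Dict]] = None,
    seed: int = 0,
    folds: int = 10,
    repeats: int = 5,
    **fit_kwargs,
) -> Dict:
    """Return the grid point with the best repeated-CV AUROC on (X, y)."""
    if grid is None:
        grid = default_grid(kind)
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if kind == "muvr_rf":
        return grid[0]
    ordered = sorted(grid, key=lambda pt: _regularization_strength(kind, pt))
    results = []
    for point in ordered:
        def fit_fn(Xtr, ytr, s, _pt=point):
            return _single_fit(kind, Xtr, ytr, _pt, s, fit_kwargs)

        mean, se = cross_val_auroc(fit_fn, _single_score, X, y, folds=folds,
                                   repeats=repeats, seed=seed, return_se=True)
        results.append((mean, se, point))
    # one-standard-error rule: among grid points whose CV AUROC is within one
    # SE of the best, take the most strongly regularized (first in order)
    best_mean, best_se, _ = max(results, key=lambda r: r[0])
    for mean, _, point in results:
        if mean >= best_mean - best_se - 1e-12:
            return dict(point, cv_auroc=mean)
    return dict(results[0][2], cv_auroc=results[0][0])


def fit_model(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[Dict] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    **kwargs,
) -> TrainedModel:
    """Fit a final model of the given kind with tuned (or default)
    hyperparameters on the full training set."""
    spec = dict(spec or {})
    spec.pop("cv_auroc", None)
    if kind == "elastic_net":
        return fit_elastic_net(X, y, alpha=spec.get("alpha", 0.5), lam=spec.get("lam", 1e-3),
                               seed=seed, feature_names=feature_names)
    if kind == "l0l2":
        if "k" in spec:
            from .linear import fit_l0l2

            return fit_l0l2(X, y, support_grid=[spec["k"]], gamma_grid=[spec.get("gamma", 1e-4)],
                            seed=seed, cv_folds=kwargs.get("cv_folds", 3), cv_repeats=1,
                            feature_names=feature_names)
        from .linear import fit_l0l2

        return fit_l0l2(X, y, seed=seed, feature_names=feature_names, **kwargs)
    if kind == "rrf":
        return fit_rrf(X, y, mtry=spec.get("mtry", 5), coef_reg=spec.get("coef_reg", 0.8),
                       seed=seed, n_trees=kwargs.get("n_trees", 500), feature_names=feature_names)
    if kind == "muvr_rf":
        return fit_muvr(X, y, n_rep=spec.get("nRep", kwargs.get("n_rep", 5)),
                        n_outer=spec.get("nOuter", kwargs.get("n_outer", 10)),
                        var_ratio=spec.get("varRatio", kwargs.get("var_ratio", 0.8)),
                        seed=seed, inner_trees=kwargs.get("inner_trees", 100),
                        final_trees=kwargs.get("final_trees", 500), feature_names=feature_names)
    raise ValueError(f"unknown model kind {kind!r}")
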