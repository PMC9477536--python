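"""Regularized logistic regression: elastic net and L0L2 best subset.

The elastic net minimizes the glmnet-style objective

    (1/n) sum_i log(1 + exp(-y_i (x_i' b + b0)))
        + lambda * (alpha * |b|_1 + (1 - alpha)/2 * |b|_2^2)

The L0L2 model solves the cardinality-constrained ridge-logistic problem
(||b||_0 <= k with ridge strength gamma) approximately, by iterative hard
thresholding with Newton polishing on the active support and a local
single-swap refinement — a faithful desk-scale stand-in for exact best-subset
solvers. The returned model never exceeds its support size.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .base import TrainedModel, sigmoid

__all__ = ["fit_elastic_net", "fit_l0l2", "fit_l0l2_single"]


def _check_Xy(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    if not np.isfinite(X).all():
        raise ValueError("X must not contain missing values")
    return X, y


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lam: float = 0.01,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Elastic-net logistic regression (saga solver, exact zeros under L1)."""
    X, y = _check_Xy(X, y)
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n = len(y)
    C = 1e12 if lam == 0 else 1.0 / (n * lam)
    est = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=C,
        max_iter=2000,
        tol=1e-7,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # near-separable data legitimately stops at the iteration cap
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    coef = est.coef_.ravel()
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(X.shape[1])]
    return TrainedModel(
        kind="elastic_net",
        hyperparameters={"alpha": alpha, "lambda": lam},
        feature_names=names,
        selected_features=[names[j] for j in np.flatnonzero(coef)],
        params={"coef": coef, "intercept": float(est.intercept_[0])},
        seed=seed,
        meta={"n": n, "pos_frac": float(y.mean())},
    )


# ---------------------------------------------------------------------------
# L0L2
# ---------------------------------------------------------------------------

def _ridge_logistic_newton(
    X: np.ndarray, y: np.ndarray, gamma: float, n_iter: int = 30, tol: float = 1e-9
) -> Tuple[np.ndarray, float]:
    """Newton solver for ridge-penalized logistic regression (unpenalized
    intercept); used to polish a fixed support."""
    n, p = X.shape
    beta = np.zeros(p)
    b0 = 0.0
    for _ in range(n_iter):
        eta = X @ beta + b0
        mu = sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-8)
        g = np.concatenate([[np.sum(mu - y) / n], X.T @ (mu - y) / n + gamma * beta])
        Xa = np.column_stack([np.ones(n), X])
        H = (Xa * w[:, None]).T @ Xa / n
        H[1:, 1:] += gamma * np.eye(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        b0 -= step[0]
        beta -= step[1:]
        if np.max(np.abs(step)) < tol:
            break
    return beta, b0


def _objective(X, y, beta, b0, gamma) -> float:
    eta = X @ beta + b0
    # numerically stable logistic loss
    loss = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return float(loss + 0.5 * gamma * beta @ beta)


def fit_l0l2_single(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    gamma: float,
    max_iter: int = 100,
    swap_passes: int = 2,
) -> Tuple[np.ndarray, float]:
    """IHT + swap refinement for one (support size, ridge strength) point.

    Returns (coef, intercept); the coefficient vector has at most k nonzeros.
    """
    n, p = X.shape
    if k > p:
        raise ValueError(f"support size {k} exceeds {p} features")
    if k == 0:
        prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return np.zeros(p), float(np.log(prev / (1 - prev)))
    # Lipschitz constant of the logistic gradient plus ridge
    L = np.linalg.norm(X, 2) ** 2 / (4.0 * n) + gamma
    beta = np.zeros(p)
    prev_mean = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    b0 = float(np.log(prev_mean / (1 - prev_mean)))
    support = np.array([], dtype=int)
    for _ in range(max_iter):
        eta = X @ beta + b0
        mu = sigmoid(eta)
        grad = X.T @ (mu - y) / n + gamma * beta
        cand = beta - grad / L
        new_support = np.sort(np.argsort(-np.abs(cand))[:k])
        beta_new = np.zeros(p)
        beta_new[new_support] = cand[new_support]
        b0 -= np.sum(mu - y) / n / L
        if np.array_equal(new_support, support) and np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
        support = new_support
    # polish on the support
    if support.size:
        bsub, b0 = _ridge_logistic_newton(X[:, support], y, gamma)
        beta = np.zeros(p)
        beta[support] = bsub

    # local combinatorial swap refinement
    for _ in range(swap_passes):
        improved = False
        obj = _objective(X, y, beta, b0, gamma)
        eta = X @ beta + b0
        mu = sigmoid(eta)
        grad_full = X.T @ (mu - y) / n
        outside = np.setdiff1d(np.arange(p), support)
        if outside.size == 0:
            break
        best_out = outside[np.argmax(np.abs(grad_full[outside]))]
        for j in support:
            trial = np.sort(np.append(np.setdiff1d(support, [j]), best_out))
            bsub, b0_t = _ridge_logistic_newton(X[:, trial], y, gamma)
            beta_t = np.zeros(p)
            beta_t[trial] = bsub
            if _objective(X, y, beta_t, b0_t, gamma) < obj - 1e-10:
                beta, b0, support = beta_t, b0_t, trial
                improved = True
                break
        if not improved:
            break
    return beta, float(b0)


def fit_l0l2(
    X: np.ndarray,
    y: np.ndarray,
    support_grid: Sequence[int] = tuple(range(0, 11)),
    gamma_grid: Sequence[float] = (1e-4, 1e-2, 1e-1),
    seed: int = 0,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """CV-selected cardinality-constrained ridge-logistic model.

    Every (k, gamma) grid point is scored by repeated stratified k-fold
    AUROC; ties break toward smaller support, then larger gamma.
    """
    from .tuning import cross_val_auroc  # local import to avoid a cycle

    X, y = _check_Xy(X, y)
    p = X.shape[1]
    for k in support_grid:
        if k > p:
            raise ValueError(f"support size {k} exceeds {p} features")
    grid = [(k, g) for k in support_grid for g in gamma_grid]
    # order so that near-ties in CV AUROC resolve toward stronger regularization
    grid.sort(key=lambda kg: (kg[0], -kg[1]))
    results = []
    for k, g in grid:
        def fit_fn(Xtr, ytr, s, _k=k, _g=g):
            coef, b0 = fit_l0l2_single(Xtr, ytr, _k, _g)
            return coef, b0

        def score_fn(model, Xte):
            coef, b0 = model
            return sigmoid(Xte @ coef + b0)

        mean, se = cross_val_auroc(fit_fn, score_fn, X, y, folds=cv_folds,
                                   repeats=cv_repeats, seed=seed, return_se=True)
        results.append((mean, se, k, g))
    best_mean, best_se, _, _ = max(results, key=lambda r: r[0])
    best = next(r for r in results if r[0] >= best_mean - best_se - 1e-12)
    _, _, k, g = best
    coef, b0 = fit_l0l2_single(X, y, k, g)
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    return TrainedModel(
        kind="l0l2",
        hyperparameters={"k": int(k), "gamma": float(g),
                         "support_grid": list(support_grid), "gamma_grid": list(gamma_grid)},
        feature_names=names,
        selected_features=[names[j] for j in np.flatnonzero(coef)],
        params={"coef": coef, "intercept": b0},
        seed=seed,
        meta={"n": len(y), "pos_frac": float(y.mean()), "cv_auroc": float(best[0])},
    )
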