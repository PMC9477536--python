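"""Patient-survival feature: Cox proportional hazards on pair alteration.

The hazard model is

    ln h(t) = ln h0 + b1 * s(A,B) + b2 * sex + b3 * age + b4 * race

where s(A,B) indicates that *both* genes of the pair are altered in a
patient's tumour (non-silent mutation, high-level CNV, or expression in the
outer 5th percentiles). The feature is the two-tailed Wald p-value of
b1 != 0. The model is fit by Newton-Raphson on the Breslow partial
likelihood; the baseline hazard h0 drops out and is never estimated.

Race enters as a single integer-coded covariate so the model has exactly the
four coefficients above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ..datatypes import OmicsBundle, canonical_pair
from .mutex import alteration_matrix

__all__ = ["CoxFit", "cox_partial_likelihood_fit", "cox_survival_feature"]


@dataclass
class CoxFit:
    beta: np.ndarray  # (b1, b2, b3, b4)
    se1: float
    wald_p: float
    n_altered: int
    converged: bool
    log_likelihood: float

    @property
    def beta1(self) -> float:
        return float(self.beta[0])


def cox_partial_likelihood_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> Optional[Tuple[np.ndarray, np.ndarray, float, bool]]:
    """Newton-Raphson on the Breslow partial likelihood.

    Returns (beta, covariance, log_likelihood, converged), or None when the
    information matrix is singular (e.g. a constant covariate).
    Convergence: relative log-likelihood change below ``tol`` or ``max_iter``
    iterations (the latter flagged as non-converged).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    # center covariates for numerical stability (invariant for Cox)
    X = X - X.mean(axis=0)

    # sort by descending time so the risk set at each event is a prefix
    order = np.argsort(-time, kind="mergesort")
    X = X[order]
    time = time[order]
    event = event[order]

    # group tied event times (Breslow: shared denominator, d events)
    beta = np.zeros(p)

    def loglik_grad_hess(b):
        eta = X @ b
        eta -= eta.max()  # guard overflow; constant shift cancels in ratios
        w = np.exp(eta)
        wX = w[:, None] * X
        cum_w = np.cumsum(w)
        cum_wX = np.cumsum(wX, axis=0)
        # cumulative sum of w * outer(x, x)
        wXX = np.einsum("i,ij,ik->ijk", w, X, X)
        cum_wXX = np.cumsum(wXX, axis=0)
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j + 1 < n and time[j + 1] == time[i]:
                j += 1
            # events at this time; risk set = indices 0..j
            ev_idx = [k for k in range(i, j + 1) if event[k] == 1]
            d = len(ev_idx)
            if d:
                S0 = cum_w[j]
                S1 = cum_wX[j]
                S2 = cum_wXX[j]
                ll += float(eta[ev_idx].sum() - d * np.log(S0))
                mu = S1 / S0
                grad += X[ev_idx].sum(axis=0) - d * mu
                hess += d * (S2 / S0 - np.outer(mu, mu))
            i = j + 1
        return ll, grad, hess

    ll_old, grad, hess = loglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        # step-halving if the likelihood does not improve
        scale = 1.0
        for _h in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = loglik_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                break
            scale *= 0.5
        else:
            return None
        beta = cand
        if np.max(np.abs(beta)) > 50:
            return beta, np.full((p, p), np.nan), ll_new, False
        rel = abs(ll_new - ll_old) / max(abs(ll_old), 1e-12)
        ll_old, grad, hess = ll_new, grad_new, hess_new
        if rel < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    return beta, cov, ll_old, converged


def cox_survival_feature(
    pair: Tuple[str, str],
    bundle: OmicsBundle,
    alt: Optional[pd.DataFrame] = None,
) -> Optional[CoxFit]:
    """Fit the pair-alteration Cox model; None when b1 is inestimable
    (alteration status constant, singular information, or no convergence).

    ``alt`` may carry a precomputed survival-mode alteration matrix.
    """
    a, b = canonical_pair(*pair)
    if alt is None:
        alt = alteration_matrix(bundle, mode="survival")
    if a not in alt.index or b not in alt.index:
        raise KeyError(f"gene missing from alteration matrix: {a!r}/{b!r}")
    s = ((alt.loc[a].to_numpy() == 1) & (alt.loc[b].to_numpy() == 1)).astype(float)
    n_altered = int(s.sum())
    if n_altered == 0 or n_altered == s.size:
        return None
    clin = bundle.clinical
    X = np.column_stack(
        [
            s,
            clin["sex"].to_numpy(dtype=float),
            clin["age"].to_numpy(dtype=float),
            clin["race"].to_numpy(dtype=float),
        ]
    )
    fit = cox_partial_likelihood_fit(X, clin["survival_days"].to_numpy(), clin["event"].to_numpy())
    if fit is None:
        return None
    beta, cov, ll, converged = fit
    if not converged or not np.isfinite(cov[0, 0]) or cov[0, 0] <= 0:
        return None
    se1 = float(np.sqrt(cov[0, 0]))
    z = beta[0] / se1
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(beta=beta, se1=se1, wald_p=wald_p, n_altered=n_altered,
                  converged=converged, log_likelihood=ll)
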