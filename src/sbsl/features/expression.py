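"""Expression features: co-expression, TMM normalization and mutation-linked
differential expression of read counts.

The differential-expression test is an edgeR-like negative-binomial exact
test: counts are TMM- and library-size-equalized, a common dispersion is
estimated across genes by method of moments, and the split of a gene's total
count between the mutated and unmutated patient groups is tested against the
conditional negative-binomial null (doubled smaller tail). The log2 fold
change uses group means of equalized counts with a 0.5 pseudocount.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ..datatypes import OmicsBundle, canonical_pair

__all__ = [
    "coexpression_features",
    "tmm_factors",
    "common_dispersion",
    "nb_exact_test",
    "diff_expression_features",
]


def coexpression_features(pair: Tuple[str, str], expr: Optional[pd.DataFrame]) -> Tuple[float, float]:
    """Pearson correlation across samples and its two-tailed t-test p-value.

    Missing (nan, nan) when the expression source is absent, a gene is absent
    or constant, or there are fewer than 3 samples.
    """
    if expr is None:
        return np.nan, np.nan
    a, b = canonical_pair(*pair)
    if a not in expr.index or b not in expr.index:
        return np.nan, np.nan
    xa = expr.loc[a].to_numpy(dtype=float)
    xb = expr.loc[b].to_numpy(dtype=float)
    if xa.size < 3:
        return np.nan, np.nan
    if np.std(xa) == 0.0 or np.std(xb) == 0.0:
        return np.nan, np.nan
    r = stats.pearsonr(xa, xb)
    return float(r.statistic), float(r.pvalue)


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3, abundance_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference is the sample whose upper quartile of library-size-scaled
    counts is closest to the mean upper quartile. M (log2 expression ratio)
    and A (mean log2 abundance) are computed over genes nonzero in both the
    sample and the reference, doubly trimmed (30% on M, 5% on A), and
    averaged with precision weights.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    scaled = mat / lib
    uq = np.array([np.quantile(scaled[:, j][scaled[:, j] > 0], 0.75) if (scaled[:, j] > 0).any() else 0.0
                   for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        both = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if both.sum() < 10:
            factors[j] = 1.0
            continue
        pj = mat[both, j] / lib[j]
        pr = mat[both, ref] / lib[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        if np.allclose(M, M[0]):
            factors[j] = 2.0 ** M[0]
            continue
        n = M.size
        lo_m, hi_m = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            factors[j] = 1.0
            continue
        cj = mat[both, j][keep]
        cr = mat[both, ref][keep]
        w = 1.0 / ((lib[j] - cj) / (lib[j] * cj) + (lib[ref] - cr) / (lib[ref] * cr))
        factors[j] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def common_dispersion(counts: pd.DataFrame, factors: Optional[pd.Series] = None) -> float:
    """Method-of-moments common NB dispersion across genes on effective-
    library-equalized counts (var = mu + phi * mu^2)."""
    if factors is None:
        factors = tmm_factors(counts)
    mat = counts.to_numpy(dtype=float)
    eff = mat.sum(axis=0) * factors.to_numpy()
    eq = mat * (np.exp(np.mean(np.log(eff))) / eff)
    mu = eq.mean(axis=1)
    var = eq.var(axis=1, ddof=1)
    ok = mu > 1.0
    if not ok.any():
        return 1e-4
    phi = (var[ok] - mu[ok]) / mu[ok] ** 2
    return float(max(np.median(phi), 1e-4))


def nb_exact_test(s1: float, n1: int, s0: float, n0: int, phi: float) -> float:
    """Doubled-tail exact-style NB test on the split of a gene's total count
    between two groups of equalized samples.

    Group sums are modelled as NB with size n_g / phi and mean n_g * mu under
    the common mean mu = (s1 + s0) / (n1 + n0); the conditional distribution
    of the group-1 sum given the total is evaluated on an adaptive window.
    """
    s1 = int(round(s1))
    s0 = int(round(s0))
    t = s1 + s0
    if t == 0:
        return np.nan
    n = n1 + n0
    mu = t / n
    r1 = n1 / phi
    r0 = n0 / phi
    m1 = n1 * mu
    m0 = n0 * mu
    # conditional support window around the mode (outside mass is negligible)
    centre = t * n1 / n
    v = (n1 * n0 / n) * (mu + phi * mu ** 2)
    half = int(max(20, 15 * np.sqrt(max(v, 1.0))))
    lo = max(0, int(centre) - half)
    hi = min(t, int(centre) + half)
    if s1 < lo:
        lo = 0
    if s1 > hi:
        hi = t
    ks = np.arange(lo, hi + 1)
    lp = (stats.nbinom.logpmf(ks, r1, r1 / (r1 + m1))
          + stats.nbinom.logpmf(t - ks, r0, r0 / (r0 + m0)))
    lp -= lp.max()
    pr = np.exp(lp)
    pr /= pr.sum()
    lower = pr[ks <= s1].sum()
    upper = pr[ks >= s1].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def diff_expression_features(
    pair: Tuple[str, str],
    bundle: OmicsBundle,
    factors: Optional[pd.Series] = None,
    dispersion: Optional[float] = None,
) -> Dict[str, float]:
    """Minimum-p orientation of the two mutation-split expression tests and
    its log2 fold change (mutated vs unmutated patients)."""
    a, b = canonical_pair(*pair)
    counts = bundle.tumour_counts
    mut = bundle.tumour_mutations
    for g in (a, b):
        if g not in counts.index or g not in mut.index:
            raise KeyError(f"gene {g!r} missing from tumour channels")
    if factors is None:
        factors = tmm_factors(counts)
    if dispersion is None:
        dispersion = common_dispersion(counts, factors)
    eff = counts.to_numpy(dtype=float).sum(axis=0) * factors.to_numpy()
    scale = np.exp(np.mean(np.log(eff))) / eff

    best: Optional[Tuple[float, float]] = None
    for gene, partner in ((a, b), (b, a)):
        x = counts.loc[gene].to_numpy(dtype=float) * scale
        grouping = mut.loc[partner].to_numpy() == 1
        n1 = int(grouping.sum())
        n0 = int((~grouping).sum())
        if n1 < 2 or n0 < 2:
            continue
        if x.sum() == 0:
            continue
        p = nb_exact_test(x[grouping].sum(), n1, x[~grouping].sum(), n0, dispersion)
        if not np.isfinite(p):
            continue
        logfc = float(np.log2((x[grouping].mean() + 0.5) / (x[~grouping].mean() + 0.5)))
        if best is None or p < best[1]:
            best = (logfc, p)
    if best is None:
        return {"diff_exp_logFC": np.nan, "diff_exp_pvalue": np.nan}
    return {"diff_exp_logFC": best[0], "diff_exp_pvalue": best[1]}
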