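"""Mutual exclusivity of somatic alterations.

Seven features quantify the tendency of alterations in two genes not to
co-occur across tumours — a classical synthetic-lethality signature:

* three per-event-type hypergeometric tests (amplification, deletion,
  non-silent mutation) plus their Fisher combination;
* a hypergeometric test on the union "alteration" event (mutation OR
  high-level CNV);
* a DISCOVER-style test with a rank-1 per-sample background and a
  Poisson-binomial null for the observed overlap;
* a margin-preserving permutation test (checkerboard-swap null).

The hypergeometric expression is evaluated verbatim as

    p = 1 - sum_{j = nAB}^{min(nA, nB)} C(nA, j) C(nT - nA, nB - j) / C(nT, nB)

i.e. the probability of *strictly fewer* co-altered samples than observed, so
strong exclusivity gives a *small* value. This lower-tail orientation is kept
deliberately (it is the published form of the feature); see the methods note
for the calibration consequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ..datatypes import OmicsBundle, canonical_pair
from ._kernels import swap_chain_overlaps, swap_chain_overlaps_multi

__all__ = [
    "MutexCounts",
    "hypergeom_exclusivity",
    "alteration_matrix",
    "discoversl_mutex_features",
    "rank1_background",
    "discover_exclusivity",
    "permutation_exclusivity",
    "permutation_exclusivity_table",
    "fisher_combine",
]


@dataclass(frozen=True)
class MutexCounts:
    """Alteration counts for a gene pair: nA, nB altered in each gene, nAB in
    both, out of nT samples."""

    nA: int
    nB: int
    nAB: int
    nT: int

    def __post_init__(self) -> None:
        if not (0 <= self.nAB <= min(self.nA, self.nB)):
            raise ValueError(f"invalid counts: nAB={self.nAB} not in [0, min(nA,nB)]")
        if max(self.nA, self.nB) > self.nT:
            raise ValueError("nA/nB exceed nT")
        if self.nA + self.nB - self.nAB > self.nT:
            raise ValueError("union of altered samples exceeds nT")


def hypergeom_exclusivity(c: MutexCounts) -> float:
    """Probability of strictly fewer co-altered samples than observed under
    the hypergeometric null; 0 when nAB = 0."""
    # 1 - P(X >= nAB) = P(X < nAB) for X ~ Hypergeom(nT, nA, nB)
    return float(stats.hypergeom.cdf(c.nAB - 1, c.nT, c.nA, c.nB))


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method over the available (non-missing) p-values."""
    ps = [p for p in pvalues if p is not None and np.isfinite(p)]
    if not ps:
        return np.nan
    ps = np.clip(np.asarray(ps, dtype=float), 1e-300, 1.0)
    chi2 = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(chi2, df=2 * len(ps)))


def alteration_matrix(bundle: OmicsBundle, mode: str = "mutex_alt") -> pd.DataFrame:
    """Binary gene x patient alteration matrix.

    ``mutex_alt``: non-silent mutation OR high-level CNV (+/-2).
    ``survival``: additionally ORs aberrant expression, defined per gene as
    a count in the upper or lower 5th percentile across patients.
    """
    if mode not in ("mutex_alt", "survival"):
        raise ValueError(f"unknown mode {mode!r}")
    mut = bundle.tumour_mutations.to_numpy() == 1
    cnv = np.abs(bundle.tumour_cnv.to_numpy()) == 2
    alt = mut | cnv
    if mode == "survival":
        x = bundle.tumour_counts.to_numpy().astype(float)
        lo = np.quantile(x, 0.05, axis=1, keepdims=True)
        hi = np.quantile(x, 0.95, axis=1, keepdims=True)
        alt |= (x <= lo) | (x >= hi)
    return pd.DataFrame(
        alt.astype(np.int8),
        index=bundle.tumour_mutations.index,
        columns=bundle.tumour_mutations.columns,
    )


def _pair_counts(ev: np.ndarray, ia: int, ib: int) -> Optional[MutexCounts]:
    nA = int(ev[ia].sum())
    nB = int(ev[ib].sum())
    if nA == 0 or nB == 0:
        return None
    nAB = int((ev[ia] & ev[ib]).sum())
    return MutexCounts(nA=nA, nB=nB, nAB=nAB, nT=ev.shape[1])


def discoversl_mutex_features(pair: Tuple[str, str], bundle: OmicsBundle) -> Dict[str, float]:
    """Per-event-type exclusivity p-values and their Fisher combination."""
    a, b = canonical_pair(*pair)
    genes = bundle.tumour_mutations.index
    if a not in genes or b not in genes:
        raise KeyError(f"gene missing from tumour channels: {a!r}/{b!r}")
    ia, ib = genes.get_loc(a), genes.get_loc(b)
    cnv = bundle.tumour_cnv.to_numpy()
    events = {
        "discoversl_mutex_amp": cnv == 2,
        "discoversl_mutex_del": cnv == -2,
        "discoversl_mutex_mut": bundle.tumour_mutations.to_numpy() == 1,
    }
    out: Dict[str, float] = {}
    for name, ev in events.items():
        c = _pair_counts(ev, ia, ib)
        out[name] = hypergeom_exclusivity(c) if c is not None else np.nan
    avail = [v for v in out.values() if np.isfinite(v)]
    out["discoversl_mutex"] = fisher_combine(avail) if avail else np.nan
    return out


# ---------------------------------------------------------------------------
# DISCOVER-style test: rank-1 background + Poisson-binomial null
# ---------------------------------------------------------------------------

def rank1_background(alt: pd.DataFrame, n_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Per-cell alteration probabilities p_gs = r_g * c_s fit by iterative
    proportional scaling to the observed gene and sample margins."""
    m = alt.to_numpy().astype(float)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    n_genes, n_samples = m.shape
    r = np.maximum(row / max(n_samples, 1), 1e-8)
    c = np.ones(n_samples)
    eps = 1e-8
    for _ in range(n_iter):
        p = np.clip(np.outer(r, c), eps, 1 - eps)
        rs = p.sum(axis=1)
        r_new = r * np.where(rs > 0, row / np.maximum(rs, eps), 1.0)
        p = np.clip(np.outer(r_new, c), eps, 1 - eps)
        cs = p.sum(axis=0)
        c_new = c * np.where(cs > 0, col / np.maximum(cs, eps), 1.0)
        if np.max(np.abs(r_new - r)) < tol and np.max(np.abs(c_new - c)) < tol:
            r, c = r_new, c_new
            break
        r, c = r_new, c_new
    return np.clip(np.outer(r, c), eps, 1 - eps)


def poisson_binomial_cdf(probs: np.ndarray, k: int) -> float:
    """P(X <= k) for a sum of independent Bernoulli(probs), by DP."""
    probs = np.asarray(probs, dtype=float)
    n = probs.size
    dp = np.zeros(n + 1)
    dp[0] = 1.0
    top = 0
    for q in probs:
        dp[1 : top + 2] = dp[1 : top + 2] * (1 - q) + dp[: top + 1] * q
        dp[0] *= 1 - q
        top += 1
    return float(dp[: k + 1].sum())


def discover_exclusivity(
    pair: Tuple[str, str],
    alt: pd.DataFrame,
    background: Optional[np.ndarray] = None,
) -> float:
    """Lower-tail Poisson-binomial probability of the observed co-alteration
    overlap under the rank-1 per-sample background."""
    a, b = canonical_pair(*pair)
    if a not in alt.index or b not in alt.index:
        raise KeyError(f"gene missing from alteration matrix: {a!r}/{b!r}")
    m = alt.to_numpy()
    ia, ib = alt.index.get_loc(a), alt.index.get_loc(b)
    if m[ia].sum() == 0 or m[ib].sum() == 0:
        return np.nan
    if background is None:
        background = rank1_background(alt)
    joint = background[ia] * background[ib]
    obs = int((m[ia] & m[ib]).sum())
    return poisson_binomial_cdf(joint, obs)


# ---------------------------------------------------------------------------
# margin-preserving permutation test
# ---------------------------------------------------------------------------

def _chain_params(alt: np.ndarray) -> Tuple[int, int]:
    nnz = int(alt.sum())
    burn_in = max(5 * nnz, 1000)
    thin = max(nnz, 200)
    return burn_in, thin


def permutation_exclusivity(
    pair: Tuple[str, str],
    alt: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for low co-alteration overlap under fixed row and
    column margins; (1 + #{overlap <= observed}) / (1 + n_perm)."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a, b = canonical_pair(*pair)
    if a not in alt.index or b not in alt.index:
        raise KeyError(f"gene missing from alteration matrix: {a!r}/{b!r}")
    m = np.ascontiguousarray(alt.to_numpy().astype(np.int8))
    ia, ib = alt.index.get_loc(a), alt.index.get_loc(b)
    obs = int(((m[ia] == 1) & (m[ib] == 1)).sum())
    burn_in, thin = _chain_params(m)
    overlaps, n_swaps = swap_chain_overlaps(m, ia, ib, int(n_perm), burn_in, thin, int(seed) + 1)
    if n_swaps == 0:
        warnings.warn("alteration matrix admits no checkerboard swap; permutation null degenerate")
        return 1.0
    return float((1 + int((overlaps <= obs).sum())) / (1 + n_perm))


def permutation_exclusivity_table(
    pairs: Sequence[Tuple[str, str]],
    alt: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for many pairs from one shared swap-chain
    ensemble (desk-scale batch variant of :func:`permutation_exclusivity`)."""
    m = np.ascontiguousarray(alt.to_numpy().astype(np.int8))
    idx = alt.index
    rows_a = np.empty(len(pairs), dtype=np.int64)
    rows_b = np.empty(len(pairs), dtype=np.int64)
    valid = np.ones(len(pairs), dtype=bool)
    for k, (a, b) in enumerate(pairs):
        a, b = canonical_pair(a, b)
        if a not in idx or b not in idx:
            valid[k] = False
            rows_a[k] = rows_b[k] = 0
            continue
        rows_a[k] = idx.get_loc(a)
        rows_b[k] = idx.get_loc(b)
    obs = np.array([int(((m[rows_a[k]] == 1) & (m[rows_b[k]] == 1)).sum()) for k in range(len(pairs))])
    burn_in, thin = _chain_params(m)
    overlaps, n_swaps = swap_chain_overlaps_multi(m, rows_a, rows_b, int(n_perm), burn_in, thin, int(seed) + 1)
    if n_swaps == 0:
        warnings.warn("alteration matrix admits no checkerboard swap; permutation null degenerate")
        out = np.ones(len(pairs))
    else:
        out = (1 + (overlaps <= obs[:, None]).sum(axis=1)) / (1 + n_perm)
    out = out.astype(float)
    out[~valid] = np.nan
    return out
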