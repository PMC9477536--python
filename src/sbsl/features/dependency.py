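"""Gene-dependency features from CRISPR/RNAi screens.

For a pair (A, B), the strongest signature of synthetic lethality in a
cell-line panel is increased essentiality (a *lower* dependency score) of one
gene in lines carrying a non-silent mutation in the other. Five features per
screen type: the rank-sum statistic and p-value of the better of the two
orientations, the Pearson correlation of the two dependency profiles with its
p-value, and the average of the two genes' mean dependency scores.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ..datatypes import canonical_pair

__all__ = ["wilcoxon_rank_sum", "dependency_features"]


def wilcoxon_rank_sum(x, y) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Exact enumeration when the pooled sample has at most 20 observations and
    no ties; otherwise normal approximation with continuity correction. The
    returned statistic is the signed standardized rank-sum statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 + n2 <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)

    # signed standardized statistic with tie-corrected variance
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    return float(z), float(res.pvalue)


def dependency_features(
    pair: Tuple[str, str],
    dep: pd.DataFrame,
    mut: pd.DataFrame,
) -> Dict[str, float]:
    """dep_stat, dep_pvalue, cor_stat, cor_pvalue and avg for one pair.

    The rank-sum test is run in both orientations — dependency of one gene
    split by the partner's mutation status — and the orientation with the
    smaller p-value is reported. An orientation with an empty mutant or
    wild-type group is skipped; if both are degenerate the test features are
    missing (the correlation and average remain defined).
    """
    a, b = canonical_pair(*pair)
    for g in (a, b):
        if g not in dep.index or g not in mut.index:
            raise KeyError(f"gene {g!r} missing from dependency/mutation matrices")
    dep_a = dep.loc[a].to_numpy(dtype=float)
    dep_b = dep.loc[b].to_numpy(dtype=float)
    mut_a = mut.loc[a].to_numpy() == 1
    mut_b = mut.loc[b].to_numpy() == 1

    best: Tuple[float, float] | None = None
    for values, grouping in ((dep_a, mut_b), (dep_b, mut_a)):
        mutant = values[grouping]
        wildtype = values[~grouping]
        if mutant.size == 0 or wildtype.size == 0:
            continue
        stat, p = wilcoxon_rank_sum(mutant, wildtype)
        if best is None or p < best[1]:
            best = (stat, p)

    if np.std(dep_a) == 0.0 or np.std(dep_b) == 0.0:
        cor_stat, cor_p = np.nan, np.nan
    elif np.allclose(dep_a, dep_b):
        cor_stat, cor_p = 1.0, 0.0
    else:
        r = stats.pearsonr(dep_a, dep_b)
        cor_stat, cor_p = float(r.statistic), float(r.pvalue)

    return {
        "dep_stat": best[0] if best is not None else np.nan,
        "dep_pvalue": best[1] if best is not None else np.nan,
        "cor_stat": cor_stat,
        "cor_pvalue": cor_p,
        "avg": float((dep_a.mean() + dep_b.mean()) / 2.0),
    }
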