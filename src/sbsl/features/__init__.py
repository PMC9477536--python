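"""The 27 molecular gene-pair features.

Every gene pair is described by 27 real-valued (possibly missing) features
drawn from five data domains: CRISPR/RNAi gene dependency (10), mutual
exclusivity of tumour alterations (7), patient survival (1), co-expression
in tumour / matched-normal / healthy-donor tissue (6), mutation-linked
differential expression (2) and pathway co-participation (1).

:func:`build_feature_table` assembles the full pairs x 27 table; per-family
functions live in the submodules and are re-exported here.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..datatypes import OmicsBundle, canonical_pair
from .dependency import dependency_features, wilcoxon_rank_sum
from .expression import (
    coexpression_features,
    common_dispersion,
    diff_expression_features,
    nb_exact_test,
    tmm_factors,
)
from .mutex import (
    MutexCounts,
    alteration_matrix,
    discover_exclusivity,
    discoversl_mutex_features,
    fisher_combine,
    hypergeom_exclusivity,
    permutation_exclusivity,
    permutation_exclusivity_table,
    rank1_background,
)
from .pathways import pathway_coparticipation
from .survival import CoxFit, cox_partial_likelihood_fit, cox_survival_feature

__all__ = [
    "FEATURE_COLUMNS",
    "PVALUE_COLUMNS",
    "build_feature_table",
    "wilcoxon_rank_sum",
    "dependency_features",
    "MutexCounts",
    "hypergeom_exclusivity",
    "alteration_matrix",
    "discoversl_mutex_features",
    "discover_exclusivity",
    "rank1_background",
    "permutation_exclusivity",
    "permutation_exclusivity_table",
    "fisher_combine",
    "CoxFit",
    "cox_partial_likelihood_fit",
    "cox_survival_feature",
    "coexpression_features",
    "tmm_factors",
    "common_dispersion",
    "nb_exact_test",
    "diff_expression_features",
    "pathway_coparticipation",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS: List[str] = [
    "CRISPR_dep_stat",
    "CRISPR_dep_pvalue",
    "CRISPR_cor_stat",
    "CRISPR_cor_pvalue",
    "CRISPR_avg",
    "RNAi_dep_stat",
    "RNAi_dep_pvalue",
    "RNAi_cor_stat",
    "RNAi_cor_pvalue",
    "RNAi_avg",
    "discoversl_mutex_amp",
    "discoversl_mutex_del",
    "discoversl_mutex_mut",
    "discoversl_mutex",
    "discover_mutex",
    "MUTEX",
    "mutex_alt",
    "logrank_pval",
    "tumour_corr",
    "tumour_pvalue",
    "normal_corr",
    "normal_pvalue",
    "gtex_corr",
    "gtex_pvalue",
    "diff_exp_logFC",
    "diff_exp_pvalue",
    "pathway_coparticipation",
]

PVALUE_COLUMNS: List[str] = [
    "CRISPR_dep_pvalue",
    "CRISPR_cor_pvalue",
    "RNAi_dep_pvalue",
    "RNAi_cor_pvalue",
    "discoversl_mutex_amp",
    "discoversl_mutex_del",
    "discoversl_mutex_mut",
    "discoversl_mutex",
    "discover_mutex",
    "MUTEX",
    "mutex_alt",
    "logrank_pval",
    "tumour_pvalue",
    "normal_pvalue",
    "gtex_pvalue",
    "diff_exp_pvalue",
    "pathway_coparticipation",
]


def build_feature_table(
    pairs: Sequence[Tuple[str, str]],
    bundle: OmicsBundle,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute all 27 features for the given gene pairs.

    The result is indexed by the canonical pair (MultiIndex gene_a/gene_b)
    and is bit-identical whichever orientation the pairs are supplied in.
    Features inestimable for a pair are missing (NaN), never zero. The
    margin-preserving permutation feature (``MUTEX``) uses one shared,
    seed-deterministic permutation ensemble for the whole table.
    """
    canon = [canonical_pair(a, b) for a, b in pairs]
    genes = bundle.genes

    # shared precomputations
    alt = alteration_matrix(bundle, mode="mutex_alt")
    alt_surv = alteration_matrix(bundle, mode="survival")
    background = rank1_background(alt)
    factors = tmm_factors(bundle.tumour_counts)
    dispersion = common_dispersion(bundle.tumour_counts, factors)

    # co-expression on log2 normalized expression: raw read counts would
    # correlate every gene pair through library size alone
    def _log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
        f = tmm_factors(counts)
        eff = counts.to_numpy(dtype=float).sum(axis=0) * f.to_numpy()
        cpm = counts.to_numpy(dtype=float) / eff * 1e6
        return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)

    tumour_expr = _log_cpm(bundle.tumour_counts)
    normal_expr = _log_cpm(bundle.normal_counts) if bundle.normal_counts is not None else None
    gtex_expr = pd.DataFrame(
        np.log2(bundle.healthy_tpm.to_numpy(dtype=float) + 1.0),
        index=bundle.healthy_tpm.index,
        columns=bundle.healthy_tpm.columns,
    )
    known = [p for p in canon if p[0] in genes and p[1] in genes]
    mutex_p = pd.Series(
        permutation_exclusivity_table(known, alt, n_perm=n_perm, seed=seed),
        index=pd.MultiIndex.from_tuples(known) if known else None,
        dtype=float,
    )

    rows = []
    for a, b in canon:
        if a not in genes or b not in genes:
            log.warning("pair (%s, %s) absent from every channel; emitting all-missing row", a, b)
            rows.append({c: np.nan for c in FEATURE_COLUMNS})
            continue
        row = {}
        dep_c = dependency_features((a, b), bundle.dependency_crispr, bundle.cellline_mutations)
        dep_r = dependency_features((a, b), bundle.dependency_rnai, bundle.cellline_mutations)
        for key, val in dep_c.items():
            row[f"CRISPR_{key}"] = val
        for key, val in dep_r.items():
            row[f"RNAi_{key}"] = val
        row.update(discoversl_mutex_features((a, b), bundle))
        row["discover_mutex"] = discover_exclusivity((a, b), alt, background=background)
        row["MUTEX"] = float(mutex_p.loc[(a, b)]) if (a, b) in mutex_p.index else np.nan
        ia, ib = genes.get_loc(a), genes.get_loc(b)
        av = alt.to_numpy()
        nA, nB = int(av[ia].sum()), int(av[ib].sum())
        if nA and nB:
            nAB = int((av[ia] & av[ib]).sum())
            row["mutex_alt"] = hypergeom_exclusivity(
                MutexCounts(nA=nA, nB=nB, nAB=nAB, nT=av.shape[1])
            )
        else:
            row["mutex_alt"] = np.nan
        fit = cox_survival_feature((a, b), bundle, alt=alt_surv)
        row["logrank_pval"] = fit.wald_p if fit is not None else np.nan
        row["tumour_corr"], row["tumour_pvalue"] = coexpression_features((a, b), tumour_expr)
        row["normal_corr"], row["normal_pvalue"] = coexpression_features((a, b), normal_expr)
        row["gtex_corr"], row["gtex_pvalue"] = coexpression_features((a, b), gtex_expr)
        row.update(diff_expression_features((a, b), bundle, factors=factors, dispersion=dispersion))
        if bundle.pathways:
            row["pathway_coparticipation"] = pathway_coparticipation((a, b), bundle.pathways)
        else:
            row["pathway_coparticipation"] = np.nan
        rows.append(row)

    index = pd.MultiIndex.from_tuples(canon, names=["gene_a", "gene_b"])
    table = pd.DataFrame(rows, index=index)
    return table[FEATURE_COLUMNS]
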