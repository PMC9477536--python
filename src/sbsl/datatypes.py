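"""Core containers: labelled gene-pair sets and multi-omics bundles.

Gene identifiers are opaque strings (HUGO symbols on real data, ``G0001``-style
ids on simulated data). A gene *pair* is always stored in canonical
(lexicographic) order so that every operation downstream is invariant to the
orientation in which a pair is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["canonical_pair", "SLLabelSet", "OmicsBundle"]


def canonical_pair(gene_a: str, gene_b: str) -> Tuple[str, str]:
    """Return the pair in canonical (lexicographic) order.

    Raises
    ------
    ValueError
        If the two genes are identical (self-pairs carry no pairwise signal).
    """
    if gene_a == gene_b:
        raise ValueError(f"self-pair not allowed: {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


LABEL_COLUMNS = ["gene_a", "gene_b", "label", "cancer", "source"]


@dataclass
class SLLabelSet:
    """Unordered labelled gene pairs with cancer-type and source tags.

    The underlying frame has columns ``gene_a, gene_b, label, cancer, source``
    with every row canonicalized and no duplicate pairs. This is the label
    *graph* whose structure must never leak into feature-based models.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in LABEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"label frame missing columns: {missing}")
        df = df[LABEL_COLUMNS].copy()
        if len(df):
            swapped = df["gene_a"] > df["gene_b"]
            if swapped.any():
                a = df.loc[swapped, "gene_b"].to_numpy()
                b = df.loc[swapped, "gene_a"].to_numpy()
                df.loc[swapped, "gene_a"] = a
                df.loc[swapped, "gene_b"] = b
            if (df["gene_a"] == df["gene_b"]).any():
                raise ValueError("self-pairs present in label set")
            dup = df.duplicated(subset=["gene_a", "gene_b"])
            if dup.any():
                raise ValueError(f"{int(dup.sum())} duplicate pair(s) in label set")
        df["label"] = df["label"].astype(int)
        if len(df) and not df["label"].isin([0, 1]).all():
            raise ValueError("labels must be 0/1")
        self.frame = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pairs(self) -> List[Tuple[str, str]]:
        return list(zip(self.frame["gene_a"], self.frame["gene_b"]))

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def genes(self) -> List[str]:
        if not len(self.frame):
            return []
        return sorted(set(self.frame["gene_a"]) | set(self.frame["gene_b"]))

    def pair_set(self) -> set:
        return set(self.pairs)

    def subset(self, mask) -> "SLLabelSet":
        return SLLabelSet(self.frame.loc[mask].reset_index(drop=True))

    @classmethod
    def from_records(
        cls,
        pairs: Iterable[Tuple[str, str]],
        labels: Iterable[int],
        cancer: str = "SYN",
        source: str = "synthetic",
    ) -> "SLLabelSet":
        pairs = [canonical_pair(a, b) for a, b in pairs]
        df = pd.DataFrame(
            {
                "gene_a": [p[0] for p in pairs],
                "gene_b": [p[1] for p in pairs],
                "label": list(labels),
                "cancer": cancer,
                "source": source,
            }
        )
        return cls(df)


@dataclass
class OmicsBundle:
    """All molecular data channels feeding the gene-pair features.

    Matrices are pandas DataFrames indexed by gene with samples as columns;
    every matrix shares the same gene index. Dependency scores follow the
    CERES/DEMETER2 convention: lower = more essential. The clinical table is
    indexed by patient id with columns ``survival_days, event, age, sex, race``.
    """

    dependency_crispr: pd.DataFrame
    dependency_rnai: pd.DataFrame
    cellline_mutations: pd.DataFrame
    tumour_mutations: pd.DataFrame
    tumour_cnv: pd.DataFrame
    tumour_counts: pd.DataFrame
    clinical: pd.DataFrame
    healthy_tpm: pd.DataFrame
    pathways: Dict[str, set]
    normal_counts: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = self.dependency_crispr.index
        for name in (
            "dependency_rnai",
            "cellline_mutations",
            "tumour_mutations",
            "tumour_cnv",
            "tumour_counts",
            "healthy_tpm",
        ):
            mat = getattr(self, name)
            if not mat.index.equals(genes):
                raise ValueError(f"{name} gene index differs from dependency_crispr")
        if self.normal_counts is not None and not self.normal_counts.index.equals(genes):
            raise ValueError("normal_counts gene index differs from dependency_crispr")
        cnv = self.tumour_cnv.to_numpy()
        if cnv.size and not np.isin(cnv, [-2, -1, 0, 1, 2]).all():
            raise ValueError("CNV values must lie in {-2,-1,0,1,2}")
        counts = self.tumour_counts.to_numpy()
        if counts.size and ((counts < 0).any() or not np.allclose(counts, np.round(counts))):
            raise ValueError("tumour counts must be nonnegative integers")
        clin = self.clinical
        required = {"survival_days", "event", "age", "sex", "race"}
        if not required.issubset(clin.columns):
            raise ValueError(f"clinical table missing columns: {required - set(clin.columns)}")
        if len(clin) and (clin["survival_days"].to_numpy() <= 0).any():
            raise ValueError("survival_days must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.dependency_crispr.index

    def has_gene(self, gene: str) -> bool:
        return gene in self.genes
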