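"""Simulation configuration.

:class:`SimConfig` collects every knob of the synthetic multi-omics generator.
Each planted effect parameter maps to exactly one feature family:

================  ========================================================
``dep_shift``     dependency-score drop of one gene in cell lines mutated
                  in its partner (units of the CRISPR score; applied
                  negatively: lower = more essential)
``excl_factor``   multiplier on the probability of *joint* tumour
                  alteration of a positive pair (1 = independent,
                  0 = perfectly exclusive)
``expr_logFC``    log2 fold change of a gene's tumour expression in
                  patients whose partner gene is mutated
``coexpr_rho``    latent co-expression of positive pairs in healthy tissue
``hazard_beta``   log hazard ratio of the designated positive pair's
                  alteration status in the survival model
``pathway_coassign`` probability a positive pair is co-assigned to at
                  least one common pathway
================  ========================================================

Setting every effect to its null value (0 for shifts, 1 for the exclusivity
factor) yields fully exchangeable positive and negative pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple

__all__ = ["SimConfig", "null_config", "planted_config"]


@dataclass
class SimConfig:
    # sizes
    n_genes: int = 300
    n_pos_pairs: int = 500
    n_neg_pairs: int = 500
    n_cell_lines: int = 100
    n_patients: int = 200
    n_healthy: int = 100

    # background rates
    mutation_rate_range: Tuple[float, float] = (0.05, 0.35)
    patient_rate_spread: float = 0.25  # lognormal sd of per-patient factor c_s
    cnv_amp_rate: float = 0.03  # per-gene rate of high-level amplification (+2)
    cnv_del_rate: float = 0.03  # high-level deletion (-2)
    cnv_low_rate: float = 0.05  # shallow +/-1 states, carry no planted signal
    counts_mean_log: float = math.log(100.0)  # log mean reads per gene
    counts_mean_sd: float = 1.0
    nb_dispersion: float = 0.15  # NB dispersion phi (var = mu + phi*mu^2)
    dep_sigma_crispr: float = 0.5
    dep_sigma_rnai: float = 0.8
    n_pathways: int = 50
    pathway_size_range: Tuple[int, int] = (10, 40)

    # planted effects (defaults are the null model)
    dep_shift: float = 0.0
    excl_factor: float = 1.0
    expr_logFC: float = 0.0
    coexpr_rho: float = 0.0
    hazard_beta: float = 0.0
    pathway_coassign: float = 0.0

    # survival nuisance structure
    hazard_beta_sex: float = 0.0
    hazard_beta_age: float = 0.0
    hazard_beta_race: float = 0.0
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censor_frac: float = 0.2

    # label-graph structure
    bias_mode: str = "uniform"  # uniform | hub | block
    hub_k: int = 5
    hub_fraction: float = 0.52
    n_blocks: int = 8
    block_noise: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_patients", "n_healthy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pos_pairs < 0 or self.n_neg_pairs < 0:
            raise ValueError("pair counts must be nonnegative")
        capacity = self.n_genes * (self.n_genes - 1) // 2
        if self.n_pos_pairs + self.n_neg_pairs > capacity:
            raise ValueError(
                f"requested {self.n_pos_pairs + self.n_neg_pairs} pairs exceed "
                f"C({self.n_genes},2) = {capacity}"
            )
        lo, hi = self.mutation_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mutation_rate_range must be an ordered interval in [0,1]")
        for name in ("excl_factor", "pathway_coassign", "censor_frac", "hub_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        if not (-1.0 <= self.coexpr_rho <= 1.0):
            raise ValueError("coexpr_rho must lie in [-1,1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("dep_sigma_crispr", "dep_sigma_rnai", "counts_mean_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bias_mode not in ("uniform", "hub", "block"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "mutation_rate_range" in d:
            d["mutation_rate_range"] = tuple(d["mutation_rate_range"])
        if "pathway_size_range" in d:
            d["pathway_size_range"] = tuple(d["pathway_size_range"])
        return cls(**d)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """All effect parameters at their null values: positives and negatives
    are statistically exchangeable and every downstream classifier should
    score chance-level AUROC."""
    return SimConfig(seed=seed, **overrides)


def planted_config(seed: int = 0, **overrides) -> SimConfig:
    """The planted-signal benchmark: every data channel carries SL signal.

    Effect sizes: dependency shift 1.0, exclusivity factor 0.3, expression
    log2FC 1.5, healthy co-expression 0.5, hazard log-ratio ln 2, pathway
    co-assignment 0.5.
    """
    defaults = dict(
        dep_shift=1.0,
        excl_factor=0.3,
        expr_logFC=1.5,
        coexpr_rho=0.5,
        hazard_beta=math.log(2.0),
        pathway_coassign=0.5,
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)
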