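"""Synthetic multi-omics generator.

Emulates, at desk scale, the data landscape behind feature-based synthetic
lethality prediction: CRISPR/RNAi dependency screens over cell-line panels,
tumour cohorts with mutation/CNV/expression-count/clinical channels, healthy
tissue expression, and pathway gene sets. Each positive pair can carry
plantable signal in exactly one data channel per effect parameter (see
:class:`~sbsl.config.SimConfig`), so every downstream feature and model is
testable without any external download.

The label generator additionally injects *gene selection bias* on demand:
``hub`` mode concentrates labels on a few genes, ``block`` mode produces
groups of genes with near-identical label rows — the two structures that make
label-topology-driven predictors look deceptively good.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .datatypes import OmicsBundle, SLLabelSet, canonical_pair

__all__ = ["gene_names", "generate_sl_labels", "generate_bundle", "generate_dataset"]

# fixed per-channel offsets for deriving child generators from the master seed
_CH = {
    "labels": 1,
    "cellline": 2,
    "dependency": 3,
    "tumour_mut": 4,
    "cnv": 5,
    "counts": 6,
    "clinical": 7,
    "healthy": 8,
    "pathways": 9,
    "normal": 10,
}


def _rng(config: SimConfig, channel: str) -> np.random.Generator:
    return np.random.default_rng([_CH[channel], config.seed])


def gene_names(n: int) -> List[str]:
    return [f"G{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def _pair_from_index(idx: int, n: int) -> Tuple[int, int]:
    # unrank an unordered pair index in row-major upper-triangular order
    i = int(n - 2 - math.floor(math.sqrt(-8 * idx + 4 * n * (n - 1) - 7) / 2 - 0.5))
    j = int(idx + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
    return i, j


def generate_sl_labels(config: SimConfig) -> SLLabelSet:
    """Draw a labelled gene-pair set under the configured bias mode.

    ``uniform`` draws pairs uniformly without replacement; ``hub``
    concentrates ``hub_fraction`` of the pairs on ``hub_k`` hub genes;
    ``block`` partitions the gene universe into ``n_blocks`` groups and gives
    all pairs between two groups the same label (flipped with probability
    ``block_noise``), emulating clustered label adjacency.
    """
    rng = _rng(config, "labels")
    n = config.n_genes
    genes = gene_names(n)
    n_pos, n_neg = config.n_pos_pairs, config.n_neg_pairs
    total = n_pos + n_neg
    if total == 0:
        return SLLabelSet.from_records([], [])

    if config.bias_mode == "uniform":
        capacity = n * (n - 1) // 2
        chosen = rng.choice(capacity, size=total, replace=False)
        pairs = [_pair_from_index(int(k), n) for k in chosen]
        labels = np.zeros(total, dtype=int)
        labels[:n_pos] = 1
        rng.shuffle(labels)
        records = [(genes[i], genes[j]) for i, j in pairs]
        return SLLabelSet.from_records(records, labels)

    if config.bias_mode == "hub":
        hubs = list(rng.choice(n, size=config.hub_k, replace=False))
        hub_set = set(hubs)
        n_hub = int(round(config.hub_fraction * total))
        seen = set()
        pairs: List[Tuple[int, int]] = []
        guard = 0
        while len(pairs) < n_hub:
            guard += 1
            if guard > 100 * total + 1000:
                raise RuntimeError("hub-mode sampling did not converge")
            h = int(rng.choice(hubs))
            p = int(rng.integers(n))
            if p == h:
                continue
            key = (min(h, p), max(h, p))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
        non_hub = [g for g in range(n) if g not in hub_set]
        guard = 0
        while len(pairs) < total:
            guard += 1
            if guard > 100 * total + 1000:
                raise RuntimeError("hub-mode sampling did not converge")
            i, j = rng.choice(len(non_hub), size=2, replace=False)
            a, b = non_hub[int(i)], non_hub[int(j)]
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
        labels = np.zeros(total, dtype=int)
        labels[:n_pos] = 1
        rng.shuffle(labels)
        records = [(genes[i], genes[j]) for i, j in pairs]
        return SLLabelSet.from_records(records, labels)

    # block mode: near-identical label rows within gene blocks
    block_of = rng.integers(config.n_blocks, size=n)
    # one shared label per unordered block pair (incl. within-block)
    nb = config.n_blocks
    block_label = {}
    for i in range(nb):
        for j in range(i, nb):
            block_label[(i, j)] = int(rng.integers(2))
    pos: List[Tuple[int, int]] = []
    neg: List[Tuple[int, int]] = []
    seen = set()
    guard = 0
    while len(pos) < n_pos or len(neg) < n_neg:
        guard += 1
        if guard > 500 * total + 10000:
            raise RuntimeError("block-mode sampling did not converge; "
                               "requested counts may exceed capacity")
        a, b = rng.choice(n, size=2, replace=False)
        a, b = int(a), int(b)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        ba, bb = sorted((block_of[a], block_of[b]))
        lab = block_label[(ba, bb)]
        if rng.random() < config.block_noise:
            lab = 1 - lab
        if lab == 1 and len(pos) < n_pos:
            seen.add(key)
            pos.append(key)
        elif lab == 0 and len(neg) < n_neg:
            seen.add(key)
            neg.append(key)
    pairs = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    records = [(genes[i], genes[j]) for i, j in pairs]
    out = SLLabelSet.from_records(records, labels)
    out.frame.attrs["block_of"] = {genes[i]: int(block_of[i]) for i in range(n)}
    return out


# ---------------------------------------------------------------------------
# omics bundle
# ---------------------------------------------------------------------------

def _positive_pairs(labels: SLLabelSet) -> List[Tuple[str, str]]:
    df = labels.frame
    return list(zip(df.loc[df["label"] == 1, "gene_a"], df.loc[df["label"] == 1, "gene_b"]))


def _thin_joint_events(mat: np.ndarray, gidx: dict, pairs, excl_factor: float,
                       rng: np.random.Generator) -> None:
    """Down-weight co-occurrence of positive pairs by removing one side of a
    joint event with probability 1 - excl_factor (approximately preserves
    margins)."""
    if excl_factor >= 1.0:
        return
    for a, b in pairs:
        ia, ib = gidx[a], gidx[b]
        joint = np.flatnonzero((mat[ia] == 1) & (mat[ib] == 1))
        if joint.size == 0:
            continue
        drop = joint[rng.random(joint.size) < (1.0 - excl_factor)]
        side = rng.random(drop.size) < 0.5
        mat[ia, drop[side]] = 0
        mat[ib, drop[~side]] = 0


def generate_bundle(labels: SLLabelSet, config: SimConfig) -> OmicsBundle:
    """Generate every omics channel with signal planted on the positive pairs.

    Identical config (including seed) yields a bit-identical bundle.
    """
    if len(labels) == 0:
        raise ValueError("label set is empty")
    genes = gene_names(config.n_genes)
    unknown = set(labels.genes()) - set(genes)
    if unknown:
        raise ValueError(f"labels reference genes outside the simulated universe: {sorted(unknown)[:5]}")
    gidx = {g: i for i, g in enumerate(genes)}
    pos_pairs = _positive_pairs(labels)
    lines = [f"CL{i:03d}" for i in range(config.n_cell_lines)]
    patients = [f"P{i:04d}" for i in range(config.n_patients)]
    healthy = [f"H{i:03d}" for i in range(config.n_healthy)]
    lo, hi = config.mutation_rate_range

    # the designated pair drives the planted survival signal; its genes are
    # given the top alteration rate so the hazard coefficient is estimable
    designated = pos_pairs[0] if pos_pairs else None

    # --- cell-line mutations and dependency screens -------------------------
    rng = _rng(config, "cellline")
    cl_rate = rng.uniform(lo, hi, size=config.n_genes)
    cl_mut = (rng.random((config.n_genes, config.n_cell_lines)) < cl_rate[:, None]).astype(np.int8)

    rng = _rng(config, "dependency")
    mu_crispr = rng.normal(-0.5, 0.3, size=config.n_genes)
    mu_rnai = rng.normal(-0.3, 0.3, size=config.n_genes)
    dep_c = rng.normal(mu_crispr[:, None], config.dep_sigma_crispr,
                       size=(config.n_genes, config.n_cell_lines))
    dep_r = rng.normal(mu_rnai[:, None], config.dep_sigma_rnai,
                       size=(config.n_genes, config.n_cell_lines))
    if config.dep_shift != 0.0:
        for a, b in pos_pairs:
            ia, ib = gidx[a], gidx[b]
            dep_c[ia, cl_mut[ib] == 1] -= config.dep_shift
            dep_c[ib, cl_mut[ia] == 1] -= config.dep_shift
            dep_r[ia, cl_mut[ib] == 1] -= config.dep_shift
            dep_r[ib, cl_mut[ia] == 1] -= config.dep_shift

    # --- tumour mutations (rank-1 background, exclusivity by thinning) ------
    rng = _rng(config, "tumour_mut")
    r_g = rng.uniform(lo, hi, size=config.n_genes)
    if designated is not None:
        r_g[gidx[designated[0]]] = hi
        r_g[gidx[designated[1]]] = hi
    sigma = config.patient_rate_spread
    c_s = rng.lognormal(-0.5 * sigma ** 2, sigma, size=config.n_patients) if sigma > 0 \
        else np.ones(config.n_patients)
    p_mut = np.clip(r_g[:, None] * c_s[None, :], 0.0, 0.95)
    t_mut = (rng.random((config.n_genes, config.n_patients)) < p_mut).astype(np.int8)
    _thin_joint_events(t_mut, gidx, pos_pairs, config.excl_factor, rng)

    # --- tumour CNV ----------------------------------------------------------
    rng = _rng(config, "cnv")
    cnv = np.zeros((config.n_genes, config.n_patients), dtype=np.int8)
    amp = (rng.random(cnv.shape) < config.cnv_amp_rate).astype(np.int8)
    dele = ((rng.random(cnv.shape) < config.cnv_del_rate) & (amp == 0)).astype(np.int8)
    _thin_joint_events(amp, gidx, pos_pairs, config.excl_factor, rng)
    _thin_joint_events(dele, gidx, pos_pairs, config.excl_factor, rng)
    cnv[amp == 1] = 2
    cnv[dele == 1] = -2
    shallow = (rng.random(cnv.shape) < config.cnv_low_rate) & (cnv == 0)
    sign = rng.random(cnv.shape) < 0.5
    cnv[shallow & sign] = 1
    cnv[shallow & ~sign] = -1

    # --- tumour read counts --------------------------------------------------
    rng = _rng(config, "counts")
    mu_g = np.exp(rng.normal(config.counts_mean_log, config.counts_mean_sd,
                             size=config.n_genes))
    libfac = np.exp(rng.normal(0.0, 0.3, size=config.n_patients))
    mean = mu_g[:, None] * libfac[None, :]
    if config.expr_logFC != 0.0:
        fc = 2.0 ** config.expr_logFC
        for a, b in pos_pairs:
            ia, ib = gidx[a], gidx[b]
            mean[ia, t_mut[ib] == 1] *= fc
            mean[ib, t_mut[ia] == 1] *= fc
    size = 1.0 / config.nb_dispersion
    t_counts = rng.negative_binomial(size, size / (size + mean)).astype(np.int64)

    # --- healthy expression (latent-factor co-expression) -------------------
    rng = _rng(config, "healthy")
    rho = abs(config.coexpr_rho)
    deg = np.zeros(config.n_genes)
    for a, b in pos_pairs:
        deg[gidx[a]] += 1
        deg[gidx[b]] += 1
    z = rng.normal(size=(config.n_genes, config.n_healthy))
    if rho > 0 and pos_pairs:
        loading = np.sqrt(np.minimum(rho, 1.0) / np.maximum(deg, 1.0))
        resid = np.sqrt(np.clip(1.0 - loading ** 2 * deg, 0.0, 1.0))
        out = z * resid[:, None]
        for a, b in pos_pairs:
            u = rng.normal(size=config.n_healthy)
            ia, ib = gidx[a], gidx[b]
            s = np.sign(config.coexpr_rho)
            out[ia] += loading[ia] * u
            out[ib] += s * loading[ib] * u
        z = out
    mu_tpm = rng.normal(2.0, 1.0, size=config.n_genes)
    healthy_tpm = np.exp(mu_tpm[:, None] + z)

    # --- matched-normal counts (same co-expression structure) ---------------
    rng = _rng(config, "normal")
    zn = rng.normal(size=(config.n_genes, config.n_healthy))
    if rho > 0 and pos_pairs:
        loading = np.sqrt(np.minimum(rho, 1.0) / np.maximum(deg, 1.0))
        resid = np.sqrt(np.clip(1.0 - loading ** 2 * deg, 0.0, 1.0))
        outn = zn * resid[:, None]
        for a, b in pos_pairs:
            u = rng.normal(size=config.n_healthy)
            ia, ib = gidx[a], gidx[b]
            s = np.sign(config.coexpr_rho)
            outn[ia] += loading[ia] * u
            outn[ib] += s * loading[ib] * u
        zn = outn
    mean_n = mu_g[:, None] * np.exp(0.75 * zn)
    normal_counts = rng.negative_binomial(size, size / (size + mean_n)).astype(np.int64)

    # --- pathways ------------------------------------------------------------
    rng = _rng(config, "pathways")
    slo, shi = config.pathway_size_range
    pathways = {}
    for k in range(config.n_pathways):
        sz = int(rng.integers(slo, shi + 1))
        members = rng.choice(config.n_genes, size=min(sz, config.n_genes), replace=False)
        pathways[f"PW{k:03d}"] = {genes[i] for i in members}
    if config.pathway_coassign > 0 and config.n_pathways > 0:
        names = list(pathways)
        for a, b in pos_pairs:
            if rng.random() < config.pathway_coassign:
                pw = names[int(rng.integers(len(names)))]
                pathways[pw].update((a, b))

    # --- clinical / survival -------------------------------------------------
    rng = _rng(config, "clinical")
    age = rng.uniform(30.0, 85.0, size=config.n_patients)
    sex = rng.integers(0, 2, size=config.n_patients)
    race = rng.choice(3, size=config.n_patients, p=[0.7, 0.2, 0.1])
    if designated is not None:
        ia, ib = gidx[designated[0]], gidx[designated[1]]
        # survival-mode alteration: mutation, high-level CNV, or expression in
        # the outer 5th percentiles across patients
        def altered(i: int) -> np.ndarray:
            x = t_counts[i].astype(float)
            lo_q, hi_q = np.quantile(x, [0.05, 0.95])
            aberrant = (x <= lo_q) | (x >= hi_q)
            return (t_mut[i] == 1) | (np.abs(cnv[i]) == 2) | aberrant
        s_ab = (altered(ia) & altered(ib)).astype(float)
    else:
        s_ab = np.zeros(config.n_patients)
    log_h = (math.log(config.baseline_hazard)
             + config.hazard_beta * s_ab
             + config.hazard_beta_sex * sex
             + config.hazard_beta_age * (age - 60.0) / 10.0
             + config.hazard_beta_race * race)
    t_event = rng.exponential(1.0 / np.exp(log_h))
    if config.censor_frac > 0:
        lam_c = config.baseline_hazard * config.censor_frac / (1.0 - config.censor_frac)
        t_cens = rng.exponential(1.0 / lam_c, size=config.n_patients)
    else:
        t_cens = np.full(config.n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival_days = np.maximum(np.ceil(time), 1.0)

    clinical = pd.DataFrame(
        {
            "survival_days": survival_days,
            "event": event,
            "age": age,
            "sex": sex,
            "race": race,
        },
        index=pd.Index(patients, name="patient"),
    )

    gi = pd.Index(genes, name="gene")
    bundle = OmicsBundle(
        dependency_crispr=pd.DataFrame(dep_c, index=gi, columns=lines),
        dependency_rnai=pd.DataFrame(dep_r, index=gi, columns=lines),
        cellline_mutations=pd.DataFrame(cl_mut, index=gi, columns=lines),
        tumour_mutations=pd.DataFrame(t_mut, index=gi, columns=patients),
        tumour_cnv=pd.DataFrame(cnv, index=gi, columns=patients),
        tumour_counts=pd.DataFrame(t_counts, index=gi, columns=patients),
        clinical=clinical,
        healthy_tpm=pd.DataFrame(healthy_tpm, index=gi, columns=healthy),
        normal_counts=pd.DataFrame(normal_counts, index=gi, columns=healthy),
        pathways=pathways,
        metadata={
            "designated_pair": designated,
            "config": config.to_dict(),
        },
    )
    return bundle


def generate_dataset(config: SimConfig) -> Tuple[SLLabelSet, OmicsBundle]:
    """Labels plus matching bundle in one call."""
    labels = generate_sl_labels(config)
    return labels, generate_bundle(labels, config)
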