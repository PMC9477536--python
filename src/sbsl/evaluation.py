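"""Bias-aware training and evaluation protocol.

Implements the full experimental harness: class balancing by uniform
downsampling, 70/30 train/test splits with three gene-holdout modes
(``none``: pair-disjoint only; ``single``: every test pair shares exactly
one gene with the train side; ``double``: train and test gene sets are
disjoint), train-only standardization and near-constant feature filtering,
repeated-CV hyperparameter tuning, AUROC/AUPRC scoring over repeated runs,
cross-dataset and grouped (pan-cancer / leave-one-cancer-out) harnesses,
permutation feature importance, variance inflation factors, and label-graph
bias diagnostics.

Everything learned from data (imputation medians, standardization moments,
filtered features, hyperparameters) is learned on the train side only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .datatypes import SLLabelSet
from .metrics import auprc, auroc
from .models import Preprocessor, TrainedModel, fit_model, predict_score, tune

__all__ = [
    "SplitPlan",
    "EvalReport",
    "balance_classes",
    "split_pairs",
    "standardize_and_filter",
    "run_experiment",
    "cross_dataset_eval",
    "grouped_eval",
    "permutation_importance",
    "vif",
    "bias_diagnostics",
    "BiasDiagnostics",
]


# ---------------------------------------------------------------------------
# balancing and splitting
# ---------------------------------------------------------------------------

def balance_classes(labels: SLLabelSet, seed: int = 0) -> SLLabelSet:
    """Uniformly downsample the majority class to the minority count."""
    df = labels.frame
    n_pos = int((df["label"] == 1).sum())
    n_neg = int((df["label"] == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return labels
    rng = np.random.default_rng(seed)
    minority = min(n_pos, n_neg)
    keep_idx = []
    for lab, count in ((1, n_pos), (0, n_neg)):
        idx = df.index[df["label"] == lab].to_numpy()
        if count > minority:
            idx = rng.choice(idx, size=minority, replace=False)
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    return SLLabelSet(df.loc[keep].reset_index(drop=True))


@dataclass
class SplitPlan:
    train: SLLabelSet
    test: SLLabelSet
    mode: str
    seed: int
    retained_fraction: float

    def validate(self) -> None:
        train_pairs = self.train.pair_set()
        test_pairs = self.test.pair_set()
        if train_pairs & test_pairs:
            raise AssertionError("train and test share pairs")
        train_genes = set(self.train.genes())
        if self.mode == "single":
            for a, b in test_pairs:
                if (a in train_genes) + (b in train_genes) != 1:
                    raise AssertionError(f"single-holdout violated for {(a, b)}")
        elif self.mode == "double":
            test_genes = set(self.test.genes())
            if train_genes & test_genes:
                raise AssertionError("double-holdout gene sets overlap")


def _holdout_gene_fraction(mode: str, test_frac: float) -> float:
    # expected test share of retained pairs as a function of the gene fraction
    if mode == "single":
        return test_frac / (2.0 - test_frac)
    s = math.sqrt(test_frac / (1.0 - test_frac))
    return s / (1.0 + s)


def split_pairs(
    labels: SLLabelSet,
    mode: str = "none",
    test_frac: float = 0.3,
    seed: int = 0,
    test_genes=None,
) -> SplitPlan:
    """Train/test split of gene pairs under a gene-holdout mode.

    ``none`` splits pairs uniformly (test size by round-half-even).
    ``single``/``double`` randomly partition the gene universe and keep the
    pairs compatible with the mode; discarded pairs are reported through
    ``retained_fraction``. ``test_genes`` fixes the held-out gene set
    explicitly instead of drawing it.
    """
    if not len(labels):
        raise ValueError("label set is empty")
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must lie in (0, 1)")
    if mode not in ("none", "single", "double"):
        raise ValueError(f"unknown holdout mode {mode!r}")
    rng = np.random.default_rng(seed)
    df = labels.frame

    if mode == "none":
        n = len(df)
        n_test = int(round(test_frac * n))  # round-half-even
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        plan = SplitPlan(
            train=SLLabelSet(df.iloc[train_idx].reset_index(drop=True)),
            test=SLLabelSet(df.iloc[test_idx].reset_index(drop=True)),
            mode=mode,
            seed=seed,
            retained_fraction=1.0,
        )
        plan.validate()
        return plan

    if test_genes is None:
        genes = labels.genes()
        rng.shuffle(genes)
        f = _holdout_gene_fraction(mode, test_frac)
        n_test_genes = max(1, int(round(f * len(genes))))
        test_genes = set(genes[:n_test_genes])
    else:
        test_genes = set(test_genes)
    a_in = df["gene_a"].isin(test_genes).to_numpy()
    b_in = df["gene_b"].isin(test_genes).to_numpy()
    train_mask = ~a_in & ~b_in
    if mode == "single":
        test_mask = a_in ^ b_in
    else:
        test_mask = a_in & b_in
    train = SLLabelSet(df.loc[train_mask].reset_index(drop=True))
    if mode == "single":
        # the train-side gene of each test pair must occur in some train pair
        train_genes_used = set(train.genes())
        tdf = df.loc[test_mask]
        keep = []
        for _, row in tdf.iterrows():
            other = row["gene_b"] if row["gene_a"] in test_genes else row["gene_a"]
            keep.append(other in train_genes_used)
        test = SLLabelSet(tdf.loc[np.array(keep, dtype=bool)].reset_index(drop=True)) if len(tdf) \
            else SLLabelSet(tdf)
    else:
        test = SLLabelSet(df.loc[test_mask].reset_index(drop=True))
    if not len(test) or not len(train):
        raise ValueError(
            f"not enough data to construct the {mode!r} holdout (train={len(train)}, test={len(test)})"
        )
    plan = SplitPlan(
        train=train,
        test=test,
        mode=mode,
        seed=seed,
        retained_fraction=(len(train) + len(test)) / len(df),
    )
    plan.validate()
    return plan


def standardize_and_filter(
    train_X: pd.DataFrame, test_X: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray, List[str], Preprocessor]:
    """Train-statistics standardization of both sides.

    Missing values are imputed with train medians before standardization;
    features whose train vector is at least 95% a single value are dropped
    from both sides. Returns the transformation for reuse at prediction time.
    """
    pre = Preprocessor.fit(train_X)
    return pre.transform(train_X), pre.transform(test_X), list(pre.feature_names), pre


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    mode: str
    runs: List[dict] = field(default_factory=list)
    importances: Dict[str, pd.Series] = field(default_factory=dict)
    vifs: Optional[pd.Series] = None
    extra: dict = field(default_factory=dict)

    def metric(self, kind: str, metric: str = "auroc") -> np.ndarray:
        return np.array([r[kind][metric] for r in self.runs if kind in r and "error" not in r])

    def summary(self) -> pd.DataFrame:
        kinds = sorted({k for r in self.runs for k in r if isinstance(r.get(k), dict)})
        rows = []
        for kind in kinds:
            for metric in ("auroc", "auprc"):
                vals = self.metric(kind, metric)
                rows.append(
                    {
                        "model": kind,
                        "metric": metric,
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "n_runs": int(vals.size),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "runs": self.runs,
            "summary": self.summary().to_dict(orient="records"),
            "importances": {k: v.to_dict() for k, v in self.importances.items()},
            "vif": self.vifs.to_dict() if self.vifs is not None else None,
            "extra": self.extra,
        }


def _pairs_xy(label_set: SLLabelSet, features: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    idx = pd.MultiIndex.from_tuples(label_set.pairs, names=["gene_a", "gene_b"])
    return features.loc[idx], label_set.labels


def _one_run(
    balanced: SLLabelSet,
    features: pd.DataFrame,
    kinds: Sequence[str],
    mode: str,
    run_seed: int,
    grids: Optional[dict],
    tune_folds: int,
    tune_repeats: int,
    model_kwargs: Optional[dict],
    importance_kind: Optional[str],
    importance_repeats: int,
    plan: Optional[SplitPlan] = None,
) -> Tuple[dict, Optional[pd.Series], Optional[pd.Series]]:
    if plan is None:
        plan = split_pairs(balanced, mode=mode, test_frac=0.3, seed=run_seed)
    Xtr_raw, ytr = _pairs_xy(plan.train, features)
    Xte_raw, yte = _pairs_xy(plan.test, features)
    Xtr, Xte, kept, pre = standardize_and_filter(Xtr_raw, Xte_raw)
    record: dict = {
        "seed": run_seed,
        "n_train": len(ytr),
        "n_test": len(yte),
        "retained_fraction": plan.retained_fraction,
    }
    imp = None
    for kind in kinds:
        kw = dict((model_kwargs or {}).get(kind, {}))
        grid = (grids or {}).get(kind)
        tune_kw = {k: kw.pop(k) for k in ("cv_trees",) if k in kw}
        spec = tune(kind, Xtr, ytr, grid=grid, seed=run_seed,
                    folds=tune_folds, repeats=tune_repeats, **tune_kw)
        model = fit_model(kind, Xtr, ytr, spec=spec, seed=run_seed,
                          feature_names=kept, **kw)
        model.preprocess = pre
        scores = predict_score(model, Xte)
        record[kind] = {
            "auroc": auroc(scores, yte),
            "auprc": auprc(scores, yte),
            "spec": {k: v for k, v in spec.items()},
        }
        if importance_kind == kind and importance_repeats > 0:
            imp = permutation_importance(model, Xte, yte, n_repeats=importance_repeats,
                                         seed=run_seed, feature_names=kept)
    return record, imp, None


def run_experiment(
    labels: SLLabelSet,
    features: pd.DataFrame,
    kinds: Sequence[str] = ("elastic_net", "l0l2", "muvr_rf", "rrf"),
    mode: str = "none",
    n_runs: int = 10,
    seed: int = 0,
    grids: Optional[dict] = None,
    tune_folds: int = 10,
    tune_repeats: int = 5,
    model_kwargs: Optional[dict] = None,
    importance_kind: Optional[str] = None,
    importance_repeats: int = 0,
    compute_vif: bool = False,
) -> EvalReport:
    """The repeated-run protocol: for each run, re-draw the class-balancing
    downsample, split under the holdout mode, standardize/filter on train,
    tune by repeated CV on train only, fit, and score the disjoint test set.

    Failed runs are recorded with their error, never silently dropped.
    """
    report = EvalReport(mode=mode)
    imps = []
    for r in range(n_runs):
        run_seed = (seed + 9973 * r) % (2 ** 31)
        try:
            balanced = balance_classes(labels, seed=run_seed)
            record, imp, _ = _one_run(
                balanced, features, kinds, mode, run_seed, grids,
                tune_folds, tune_repeats, model_kwargs,
                importance_kind, importance_repeats,
            )
        except Exception as exc:  # recorded, not dropped
            record, imp = {"seed": run_seed, "error": f"{type(exc).__name__}: {exc}"}, None
        report.runs.append(record)
        if imp is not None:
            imps.append(imp)
    if imps:
        report.importances[importance_kind or ""] = pd.concat(imps, axis=1).mean(axis=1)
        report.extra["importance_runs"] = [s.to_dict() for s in imps]
    if compute_vif:
        idx = pd.MultiIndex.from_tuples(labels.pairs, names=["gene_a", "gene_b"])
        Xall = features.loc[idx]
        pre = Preprocessor.fit(Xall)
        report.vifs = vif(pd.DataFrame(pre.transform(Xall), columns=pre.feature_names))
    return report


def cross_dataset_eval(
    train_labels: SLLabelSet,
    test_labels: SLLabelSet,
    features: pd.DataFrame,
    kinds: Sequence[str] = ("elastic_net", "l0l2", "muvr_rf", "rrf"),
    n_runs: int = 10,
    seed: int = 0,
    **kwargs,
) -> EvalReport:
    """Train on one label source, test on another; pairs labelled in both
    sets are removed from the train side only."""
    shared = train_labels.pair_set() & test_labels.pair_set()
    mask = [p not in shared for p in train_labels.pairs]
    train_clean = train_labels.subset(np.array(mask, dtype=bool))
    if not len(train_clean):
        raise ValueError("train set empty after removing pairs shared with the test set")
    report = EvalReport(mode="cross_dataset")
    report.extra["n_removed_from_train"] = len(shared)
    for r in range(n_runs):
        run_seed = (seed + 9973 * r) % (2 ** 31)
        try:
            tr = balance_classes(train_clean, seed=run_seed)
            te = balance_classes(test_labels, seed=run_seed + 1)
            plan = SplitPlan(train=tr, test=te, mode="cross_dataset", seed=run_seed,
                             retained_fraction=len(tr) / len(train_labels))
            record, _, _ = _one_run(
                tr, features, kinds, "none", run_seed,
                kwargs.get("grids"), kwargs.get("tune_folds", 10),
                kwargs.get("tune_repeats", 5), kwargs.get("model_kwargs"),
                None, 0, plan=plan,
            )
        except Exception as exc:
            record = {"seed": run_seed, "error": f"{type(exc).__name__}: {exc}"}
        report.runs.append(record)
    return report


def grouped_eval(
    labels: SLLabelSet,
    features: pd.DataFrame,
    kinds: Sequence[str] = ("l0l2", "muvr_rf"),
    held_out_group: Optional[str] = None,
    balance: str = "balanced",
    n_runs: int = 10,
    seed: int = 0,
    **kwargs,
) -> EvalReport:
    """Pan-cancer / leave-one-cancer-out harness over the ``cancer`` column.

    LOCO (``held_out_group`` set): train on every other group, test on the
    held-out one. Pan-cancer (``held_out_group`` None): per run, split each
    group 70/30, train on the union (``balanced``: equal group x class counts
    by undersampling; ``unbalanced``: native proportions) and report
    per-group test metrics.
    """
    if balance not in ("balanced", "unbalanced"):
        raise ValueError("balance must be 'balanced' or 'unbalanced'")
    df = labels.frame
    groups = sorted(df["cancer"].unique())
    if len(groups) < 2:
        raise ValueError("grouped evaluation needs at least two groups")

    def _balance_groups(sub: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        counts = sub.groupby(["cancer", "label"]).size()
        if counts.empty or (counts == 0).any():
            raise ValueError("a group is missing a class; cannot balance")
        m = int(counts.min())
        takes = []
        for (g, l), _ in counts.items():
            idx = sub.index[(sub["cancer"] == g) & (sub["label"] == l)].to_numpy()
            takes.append(rng.choice(idx, size=m, replace=False))
        return sub.loc[np.sort(np.concatenate(takes))]

    report = EvalReport(mode=f"loco:{held_out_group}" if held_out_group else f"pan:{balance}")
    for r in range(n_runs):
        run_seed = (seed + 9973 * r) % (2 ** 31)
        rng = np.random.default_rng(run_seed)
        try:
            if held_out_group is not None:
                if held_out_group not in groups:
                    raise ValueError(f"unknown group {held_out_group!r}")
                tr_df = df[df["cancer"] != held_out_group]
                te_df = df[df["cancer"] == held_out_group]
                if balance == "balanced":
                    tr_df = _balance_groups(tr_df, rng)
                tr = balance_classes(SLLabelSet(tr_df.reset_index(drop=True)), seed=run_seed)
                te = balance_classes(SLLabelSet(te_df.reset_index(drop=True)), seed=run_seed + 1)
                plan = SplitPlan(train=tr, test=te, mode="loco", seed=run_seed, retained_fraction=1.0)
                record, _, _ = _one_run(
                    tr, features, kinds, "none", run_seed,
                    kwargs.get("grids"), kwargs.get("tune_folds", 10),
                    kwargs.get("tune_repeats", 5), kwargs.get("model_kwargs"),
                    None, 0, plan=plan,
                )
            else:
                tr_parts, te_parts = [], []
                for g in groups:
                    sub = SLLabelSet(df[df["cancer"] == g].reset_index(drop=True))
                    plan_g = split_pairs(sub, mode="none", test_frac=0.3, seed=run_seed + hash(g) % 1000)
                    tr_parts.append(plan_g.train.frame)
                    te_parts.append(plan_g.test.frame)
                tr_df = pd.concat(tr_parts, ignore_index=True)
                if balance == "balanced":
                    tr_df = _balance_groups(tr_df, rng).reset_index(drop=True)
                tr = SLLabelSet(tr_df)
                record = {"seed": run_seed}
                Xtr_raw, ytr = _pairs_xy(tr, features)
                pre = Preprocessor.fit(Xtr_raw)
                Xtr = pre.transform(Xtr_raw)
                for kind in kinds:
                    kw = dict((kwargs.get("model_kwargs") or {}).get(kind, {}))
                    tune_kw = {k: kw.pop(k) for k in ("cv_trees",) if k in kw}
                    spec = tune(kind, Xtr, ytr, grid=(kwargs.get("grids") or {}).get(kind),
                                seed=run_seed, folds=kwargs.get("tune_folds", 10),
                                repeats=kwargs.get("tune_repeats", 5), **tune_kw)
                    model = fit_model(kind, Xtr, ytr, spec=spec, seed=run_seed,
                                      feature_names=list(pre.feature_names), **kw)
                    model.preprocess = pre
                    per_group = {}
                    for g, te_df in zip(groups, te_parts):
                        te = SLLabelSet(te_df.reset_index(drop=True))
                        Xte_raw, yte = _pairs_xy(te, features)
                        scores = predict_score(model, pre.transform(Xte_raw))
                        if np.unique(yte).size < 2:
                            per_group[g] = {"auroc": np.nan, "auprc": np.nan}
                        else:
                            per_group[g] = {"auroc": auroc(scores, yte), "auprc": auprc(scores, yte)}
                    record[kind] = {"per_group": per_group,
                                    "auroc": float(np.nanmean([v["auroc"] for v in per_group.values()])),
                                    "auprc": float(np.nanmean([v["auprc"] for v in per_group.values()]))}
        except Exception as exc:
            record = {"seed": run_seed, "error": f"{type(exc).__name__}: {exc}"}
        report.runs.append(record)
    return report


# ---------------------------------------------------------------------------
# importance, collinearity, bias diagnostics
# ---------------------------------------------------------------------------

def permutation_importance(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Mean AUROC drop when a feature column is permuted within itself."""
    X = np.asarray(X, dtype=float)
    names = list(feature_names) if feature_names is not None else list(model.feature_names)
    rng = np.random.default_rng(seed)
    base = auroc(predict_score(model, X), y)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j] += base - auroc(predict_score(model, Xp), y)
    return pd.Series(drops / n_repeats, index=names, name="delta_auroc")


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature: 1 / (1 - R^2) from regressing
    each feature on all others (with intercept). Exact collinearity is
    reported as +inf."""
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    if n <= p:
        raise ValueError("need more samples than features for VIF")
    if (arr.std(axis=0) == 0).any():
        raise ValueError("constant column in VIF input")
    out = np.empty(p)
    for j in range(p):
        yj = arr[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        sst = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / sst
        out[j] = np.inf if r2 > 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=X.columns, name="vif")


@dataclass
class BiasDiagnostics:
    n_genes: int
    n_pairs: int
    labelled_fraction: float  # pairs / C(genes, 2)
    labelled_fraction_half_square: float  # pairs / (genes^2 / 2)
    degrees: pd.Series
    top_genes: List[str]
    top_gene_coverage: float
    adjacency: pd.DataFrame  # +1 / -1 / 0, clustering-ordered
    linkage_matrix: np.ndarray
    gene_order: List[str]  # original (sorted) order the linkage was built on

    def cluster_assignments(self, n_clusters: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.gene_order, name="cluster")

    def summary(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_pairs": self.n_pairs,
            "labelled_fraction": self.labelled_fraction,
            "labelled_fraction_half_square": self.labelled_fraction_half_square,
            "top_genes": self.top_genes,
            "top_gene_coverage": self.top_gene_coverage,
            "max_degree": int(self.degrees.max()),
        }


def bias_diagnostics(labels: SLLabelSet, coverage_fraction: float = 0.5) -> BiasDiagnostics:
    """Label-graph structure report.

    The signed adjacency (+1 positive, -1 negative, 0 unlabelled) is ordered
    by complete-linkage hierarchical clustering with Euclidean distance on
    its rows (columns follow rows); also reports per-gene degrees, the
    labelled fraction under both natural denominators, and the greedy
    minimal gene set covering at least ``coverage_fraction`` of the pairs.
    """
    if not len(labels):
        raise ValueError("label set is empty")
    genes = labels.genes()
    g = len(genes)
    gidx = {x: i for i, x in enumerate(genes)}
    adj = np.zeros((g, g), dtype=np.int8)
    for (a, b), lab in zip(labels.pairs, labels.labels):
        v = 1 if lab == 1 else -1
        adj[gidx[a], gidx[b]] = v
        adj[gidx[b], gidx[a]] = v
    degrees = pd.Series((adj != 0).sum(axis=1), index=genes, name="degree")

    # greedy minimal covering gene set
    pair_list = labels.pairs
    n_pairs = len(pair_list)
    covered = np.zeros(n_pairs, dtype=bool)
    top: List[str] = []
    target = coverage_fraction * n_pairs
    while covered.sum() < target:
        counts: Dict[str, int] = {}
        for i, (a, b) in enumerate(pair_list):
            if not covered[i]:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        best = max(sorted(counts), key=counts.get)
        top.append(best)
        for i, (a, b) in enumerate(pair_list):
            if best in (a, b):
                covered[i] = True
    coverage = float(covered.sum()) / n_pairs

    if g > 2:
        with warnings.catch_warnings():
            # rows of the signed adjacency are the observations on purpose
            warnings.simplefilter("ignore")
            Z = linkage(adj.astype(float), method="complete", metric="euclidean")
        order = leaves_list(Z)
    else:
        Z = np.zeros((0, 4))
        order = np.arange(g)
    ordered_genes = [genes[i] for i in order]
    adjacency = pd.DataFrame(adj, index=genes, columns=genes).loc[ordered_genes, ordered_genes]

    return BiasDiagnostics(
        n_genes=g,
        n_pairs=n_pairs,
        labelled_fraction=n_pairs / (g * (g - 1) / 2),
        labelled_fraction_half_square=n_pairs / (g * g / 2),
        degrees=degrees,
        top_genes=top,
        top_gene_coverage=coverage,
        adjacency=adjacency,
        linkage_matrix=Z,
        gene_order=genes,
    )
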