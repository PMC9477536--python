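"""Evaluation-harness contracts: balancing, holdout splits, leakage-free
standardization, metrics against brute force, VIF, importance, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sbsl
from sbsl.datatypes import SLLabelSet
from sbsl.evaluation import (
    balance_classes,
    bias_diagnostics,
    cross_dataset_eval,
    permutation_importance,
    split_pairs,
    standardize_and_filter,
    vif,
)
from sbsl.metrics import auprc, auroc
from sbsl.models import Preprocessor, fit_elastic_net


def _labels(pairs, labels, cancer="SYN"):
    return SLLabelSet.from_records(pairs, labels, cancer=cancer)


class TestBalance:
    def test_downsamples_majority_only(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(60)]
        pairs = list(itertools.combinations(genes, 2))[:800]
        labs = [1] * 100 + [0] * 700
        ls = _labels(pairs, labs)
        bal = balance_classes(ls, seed=1)
        assert (bal.labels == 1).sum() == 100
        assert (bal.labels == 0).sum() == 100
        # minority untouched
        pos_before = {p for p, l in zip(ls.pairs, ls.labels) if l == 1}
        pos_after = {p for p, l in zip(bal.pairs, bal.labels) if l == 1}
        assert pos_before == pos_after

    def test_already_balanced_unchanged_and_deterministic(self):
        pairs = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")]
        ls = _labels(pairs, [1, 1, 0, 0])
        assert balance_classes(ls, seed=0).frame.equals(ls.frame)
        big = _labels(list(itertools.combinations([f"G{i}" for i in range(30)], 2))[:200],
                      [1] * 50 + [0] * 150)
        assert balance_classes(big, seed=9).frame.equals(balance_classes(big, seed=9).frame)

    def test_single_class_rejected(self):
        ls = _labels([("A", "B")], [1])
        with pytest.raises(ValueError):
            balance_classes(ls, seed=0)


class TestSplit:
    def test_toy_double_holdout_enumeration(self):
        ls = _labels([("A", "B"), ("A", "C"), ("B", "D"), ("C", "E"), ("D", "F"), ("E", "F")],
                     [1, 0, 1, 0, 1, 0])
        plan = split_pairs(ls, mode="double", test_genes={"E", "F"})
        assert plan.test.pair_set() == {("E", "F")}
        assert plan.train.pair_set() == {("A", "B"), ("A", "C"), ("B", "D")}
        assert plan.retained_fraction == pytest.approx(4 / 6)

    def test_none_mode_sizes_round_half_even(self):
        genes = [f"G{i:03d}" for i in range(120)]
        pairs = list(itertools.combinations(genes, 2))[:1098]
        ls = _labels(pairs, [i % 2 for i in range(1098)])
        plan = split_pairs(ls, mode="none", test_frac=0.3, seed=0)
        assert len(plan.test) == 329
        assert len(plan.train) == 769

    @pytest.mark.parametrize("mode", ["none", "single", "double"])
    def test_invariants_over_many_seeds(self, mode):
        genes = [f"G{i:03d}" for i in range(40)]
        rng = np.random.default_rng(0)
        all_pairs = list(itertools.combinations(genes, 2))
        chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), 250, replace=False)]
        ls = _labels(chosen, rng.integers(0, 2, 250))
        for seed in range(40):
            plan = split_pairs(ls, mode=mode, seed=seed)
            plan.validate()  # raises on any invariant violation
            if mode == "single":
                train_genes = set(plan.train.genes())
                for a, b in plan.test.pairs:
                    assert (a in train_genes) + (b in train_genes) == 1
            if mode == "double":
                assert not set(plan.train.genes()) & set(plan.test.genes())

    def test_double_infeasible_on_tiny_clique(self):
        ls = _labels([("A", "B"), ("A", "C"), ("B", "C")], [1, 0, 1])
        with pytest.raises(ValueError):
            split_pairs(ls, mode="double", test_genes={"A"})


class TestStandardizeAndFilter:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(0)
        tr = pd.DataFrame(rng.normal(2.0, 3.0, size=(100, 4)), columns=list("abcd"))
        te = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        Xtr, Xte, kept, _ = standardize_and_filter(tr, te)
        assert kept == list("abcd")
        np.testing.assert_allclose(Xtr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xtr.std(axis=0), 1.0, atol=1e-12)

    def test_near_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        tr = pd.DataFrame({"ok": rng.normal(size=100),
                           "const96": np.r_[np.zeros(96), rng.normal(size=4)]})
        te = tr.copy()
        _, _, kept, _ = standardize_and_filter(tr, te)
        assert kept == ["ok"]

    def test_test_outlier_does_not_leak_into_statistics(self):
        rng = np.random.default_rng(2)
        tr = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        te = tr.iloc[:10].copy()
        _, Xte_clean, _, pre_clean = standardize_and_filter(tr, te)
        te_outlier = te.copy()
        te_outlier.iloc[0, 0] = 1e9
        _, Xte_out, _, pre_out = standardize_and_filter(tr, te_outlier)
        np.testing.assert_array_equal(pre_clean.means, pre_out.means)
        np.testing.assert_array_equal(pre_clean.sds, pre_out.sds)
        np.testing.assert_array_equal(Xte_clean[1:], Xte_out[1:])

    def test_all_filtered_raises(self):
        tr = pd.DataFrame({"c": np.ones(50)})
        with pytest.raises(ValueError):
            standardize_and_filter(tr, tr.copy())


class TestMetrics:
    def test_perfect_and_tied_scores(self):
        y = np.array([1, 0, 1, 0])
        assert auroc(y.astype(float), y) == 1.0
        assert auprc(y.astype(float), y) == 1.0
        tied = np.full(4, 0.7)
        assert auroc(tied, y) == 0.5
        assert auprc(tied, y) == pytest.approx(0.5)

    def test_four_point_toy(self):
        assert auroc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(3)
        for n in (20, 100, 200):
            scores = np.round(rng.random(n), 2)  # force some ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            pos = scores[y == 1]
            neg = scores[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc(scores, y) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestVif:
    def test_orthonormal_design(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(300, 4)))
        out = vif(pd.DataFrame(q, columns=list("abcd")))
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-3)

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        out = vif(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=200)}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_bivariate_closed_form(self):
        rng = np.random.default_rng(2)
        n = 60000
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        z = rng.normal(size=n)
        out = vif(pd.DataFrame({"x": x, "y": y, "z": z}))
        assert out["x"] == pytest.approx(1 / (1 - 0.64), rel=0.05)


class TestPermutationImportance:
    def test_unused_feature_has_no_importance(self, toy_classification):
        X, y = toy_classification
        m = fit_elastic_net(X, y, alpha=1.0, lam=5e-2)  # sparse: noise coefs 0
        imp = permutation_importance(m, X, y, n_repeats=5, seed=0)
        zero_feats = [f"f{j}" for j in range(X.shape[1]) if m.params["coef"][j] == 0]
        assert zero_feats, "expected some exactly-zero coefficients"
        assert all(abs(imp[f]) < 0.01 for f in zero_feats)
        assert imp["f4"] == imp.max()

    def test_permuting_everything_destroys_ranking(self, toy_classification):
        X, y = toy_classification
        m = fit_elastic_net(X, y, alpha=0.5, lam=1e-3)
        rng = np.random.default_rng(0)
        Xp = rng.permutation(X, axis=0)
        from sbsl.models import predict_score

        assert abs(auroc(predict_score(m, Xp), y) - 0.5) < 0.08


class TestBiasDiagnostics:
    def test_labelled_fraction_conventions(self):
        cfg = sbsl.null_config(seed=1, n_genes=86, n_pos_pairs=223, n_neg_pairs=449)
        labels = sbsl.generate_sl_labels(cfg)
        g = len(labels.genes())
        diag = bias_diagnostics(labels)
        assert diag.n_pairs == 672
        assert diag.labelled_fraction == pytest.approx(672 / (g * (g - 1) / 2))
        assert diag.labelled_fraction_half_square == pytest.approx(672 / (g * g / 2))

    def test_clique_degrees(self):
        genes = list("ABCDE")
        pairs = list(itertools.combinations(genes, 2))
        diag = bias_diagnostics(_labels(pairs, [1] * len(pairs)))
        assert (diag.degrees == 4).all()
        assert diag.labelled_fraction == 1.0

    def test_block_structure_recovered_by_clustering(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = sbsl.null_config(seed=4, n_genes=36, n_pos_pairs=250, n_neg_pairs=250,
                               bias_mode="block", n_blocks=3, block_noise=0.02)
        labels = sbsl.generate_sl_labels(cfg)
        block_of = labels.frame.attrs["block_of"]
        diag = bias_diagnostics(labels)
        found = diag.cluster_assignments(3)
        truth = [block_of[g] for g in found.index]
        assert adjusted_rand_score(truth, found.to_numpy()) > 0.8


class TestCrossDataset:
    def test_total_overlap_is_infeasible(self, planted_small, planted_small_features):
        _, labels, _ = planted_small
        with pytest.raises(ValueError, match="empty"):
            cross_dataset_eval(labels, labels, planted_small_features, n_runs=1)

    def test_disjoint_sets_remove_nothing(self, planted_small, planted_small_features):
        _, labels, _ = planted_small
        half = len(labels) // 2
        a = labels.subset(labels.frame.index < half)
        b = labels.subset(labels.frame.index >= half)
        rep = cross_dataset_eval(a, b, planted_small_features,
                                 kinds=("elastic_net",), n_runs=1,
                                 tune_folds=3, tune_repeats=1,
                                 grids={"elastic_net": [{"alpha": 0.5, "lam": 1e-3}]})
        assert rep.extra["n_removed_from_train"] == 0
        assert "elastic_net" in rep.runs[0]
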