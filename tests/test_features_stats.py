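"""Statistical primitives behind the features, checked against independent
oracles: rank-assignment enumeration (Wilcoxon), subset enumeration
(hypergeometric), outcome enumeration (Poisson-binomial), exhaustive
margin-preserving matrices (permutation test), and lifelines (Cox)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sbsl
from sbsl.features import (
    MutexCounts,
    alteration_matrix,
    cox_partial_likelihood_fit,
    cox_survival_feature,
    coexpression_features,
    dependency_features,
    discover_exclusivity,
    discoversl_mutex_features,
    hypergeom_exclusivity,
    nb_exact_test,
    pathway_coparticipation,
    permutation_exclusivity,
    tmm_factors,
    wilcoxon_rank_sum,
)
from sbsl.features.mutex import poisson_binomial_cdf


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _enum_ranksum_p(x, y):
    """Exact two-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs_u = stats.mannwhitneyu(x, y, method="exact").statistic
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(comb)].sum()
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return min(1.0, 2 * min((us <= obs_u).mean(), (us >= obs_u).mean()))


class TestWilcoxon:
    def test_most_extreme_assignment(self):
        stat, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)
        assert stat < 0

    @pytest.mark.parametrize("trial", range(25))
    def test_exact_matches_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n1, n2 = rng.integers(1, 9, size=2)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_enum_ranksum_p(x, y), abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([5.0], [])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))[1] for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# hypergeometric exclusivity
# ---------------------------------------------------------------------------

def _enum_hypergeom(nT, nA, nB, nAB):
    """P(strictly fewer co-altered) by enumerating all size-nB subsets."""
    a_set = set(range(nA))
    total = fewer = 0
    for subset in itertools.combinations(range(nT), nB):
        total += 1
        if len(a_set & set(subset)) < nAB:
            fewer += 1
    return fewer / total


class TestHypergeom:
    def test_worked_example(self):
        assert hypergeom_exclusivity(MutexCounts(nA=4, nB=5, nAB=2, nT=10)) == pytest.approx(66 / 252)

    def test_zero_overlap_gives_zero(self):
        assert hypergeom_exclusivity(MutexCounts(nA=3, nB=4, nAB=0, nT=10)) == 0.0

    def test_matches_subset_enumeration(self):
        for nT in (4, 6, 8):
            for nA in range(1, nT + 1):
                for nB in range(1, nT + 1):
                    lo = max(0, nA + nB - nT)
                    for nAB in range(lo, min(nA, nB) + 1):
                        p = hypergeom_exclusivity(MutexCounts(nA=nA, nB=nB, nAB=nAB, nT=nT))
                        assert p == pytest.approx(_enum_hypergeom(nT, nA, nB, nAB), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            MutexCounts(nA=2, nB=2, nAB=3, nT=10)
        with pytest.raises(ValueError):
            MutexCounts(nA=8, nB=8, nAB=1, nT=10)


# ---------------------------------------------------------------------------
# Poisson-binomial / DISCOVER
# ---------------------------------------------------------------------------

def _brute_poisson_binomial_cdf(probs, k):
    total = 0.0
    n = len(probs)
    for bits in itertools.product([0, 1], repeat=n):
        pr = math.prod(p if b else 1 - p for p, b in zip(probs, bits))
        if sum(bits) <= k:
            total += pr
    return total


class TestDiscover:
    def test_two_coin_example(self):
        assert poisson_binomial_cdf(np.array([0.5, 0.5]), 1) == pytest.approx(0.75)

    def test_point_mass(self):
        assert poisson_binomial_cdf(np.zeros(5), 0) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 7, 12])
    def test_dp_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        probs = rng.random(n)
        for k in (0, n // 2, n):
            assert poisson_binomial_cdf(probs, k) == pytest.approx(
                _brute_poisson_binomial_cdf(probs, k), abs=1e-12
            )

    def test_agrees_with_hypergeom_under_uniform_margins(self):
        """With exchangeable samples the rank-1 background is flat and the
        DISCOVER tail must order pairs like the hypergeometric tail."""
        rng = np.random.default_rng(4)
        n_genes, n_samples = 40, 60
        alt = pd.DataFrame(
            (rng.random((n_genes, n_samples)) < 0.25).astype(np.int8),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
        disc, hyp = [], []
        av = alt.to_numpy()
        for _ in range(100):
            i, j = rng.choice(n_genes, size=2, replace=False)
            nA, nB = int(av[i].sum()), int(av[j].sum())
            if nA == 0 or nB == 0:
                continue
            nAB = int((av[i] & av[j]).sum())
            disc.append(discover_exclusivity((alt.index[i], alt.index[j]), alt))
            hyp.append(hypergeom_exclusivity(MutexCounts(nA=nA, nB=nB, nAB=nAB, nT=n_samples)))
        rho = stats.spearmanr(disc, hyp).statistic
        assert rho > 0.9

    def test_never_altered_gene_is_missing(self):
        alt = pd.DataFrame([[1, 1, 0], [0, 0, 0]], index=["A", "B"], columns=list("xyz"))
        assert np.isnan(discover_exclusivity(("A", "B"), alt))


# ---------------------------------------------------------------------------
# margin-preserving permutation test
# ---------------------------------------------------------------------------

def _enum_margin_matrices(mat):
    """All binary matrices with the same row and column sums (tiny inputs)."""
    rows, cols = mat.shape
    rsum = mat.sum(axis=1)
    csum = mat.sum(axis=0)
    out = []
    for bits in itertools.product([0, 1], repeat=rows * cols):
        cand = np.array(bits).reshape(rows, cols)
        if (cand.sum(axis=1) == rsum).all() and (cand.sum(axis=0) == csum).all():
            out.append(cand)
    return out


class TestPermutationExclusivity:
    def test_maximum_overlap_gives_one(self):
        mat = np.zeros((6, 8), dtype=np.int8)
        mat[0, :4] = 1
        mat[1, :4] = 1
        mat[2, 4:] = 1
        mat[3, 4:] = 1
        alt = pd.DataFrame(mat, index=[f"G{i}" for i in range(6)], columns=[f"S{j}" for j in range(8)])
        p = permutation_exclusivity(("G0", "G1"), alt, n_perm=200, seed=0)
        assert p == pytest.approx(1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        alt = pd.DataFrame((rng.random((10, 20)) < 0.3).astype(np.int8),
                           index=[f"G{i}" for i in range(10)],
                           columns=[f"S{j}" for j in range(20)])
        p1 = permutation_exclusivity(("G0", "G1"), alt, n_perm=300, seed=7)
        p2 = permutation_exclusivity(("G0", "G1"), alt, n_perm=300, seed=7)
        assert p1 == p2

    def test_matches_exhaustive_null_on_small_matrix(self):
        mat = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 1]], dtype=np.int8)
        alt = pd.DataFrame(mat, index=list("ABCD"), columns=list("wxyz"))
        obs = int((mat[0] & mat[1]).sum())
        universe = _enum_margin_matrices(mat)
        exact = np.mean([int((m[0] & m[1]).sum()) <= obs for m in universe])
        p = permutation_exclusivity(("A", "B"), alt, n_perm=10000, seed=3)
        assert p == pytest.approx(exact, abs=0.02)


# ---------------------------------------------------------------------------
# alteration matrix and per-type features
# ---------------------------------------------------------------------------

class TestAlterationMatrix:
    def test_shallow_cnv_does_not_count(self, null_small):
        _, _, bundle = null_small
        alt = alteration_matrix(bundle, mode="mutex_alt")
        manual = (bundle.tumour_mutations.to_numpy() == 1) | (np.abs(bundle.tumour_cnv.to_numpy()) == 2)
        assert np.array_equal(alt.to_numpy().astype(bool), manual)

    def test_survival_mode_adds_expression_tails(self, null_small):
        _, _, bundle = null_small
        base = alteration_matrix(bundle, mode="mutex_alt").to_numpy()
        surv = alteration_matrix(bundle, mode="survival").to_numpy()
        assert (surv >= base).all()
        # both 5th-percentile tails: at least ~10% of patients per gene
        extra = (surv == 1).mean(axis=1)
        assert (extra >= 0.10 - 1e-9).all()

    def test_no_cnv_events_degrades_gracefully(self, null_small):
        _, labels, bundle = null_small
        import copy

        b2 = copy.copy(bundle)
        b2.tumour_cnv = bundle.tumour_cnv * 0
        pair = labels.pairs[0]
        feats = discoversl_mutex_features(pair, b2)
        assert np.isnan(feats["discoversl_mutex_amp"])
        assert np.isnan(feats["discoversl_mutex_del"])
        assert np.isfinite(feats["discoversl_mutex_mut"])
        # combined over a single available type equals that type's p-value
        assert feats["discoversl_mutex"] == pytest.approx(feats["discoversl_mutex_mut"], abs=1e-9)


# ---------------------------------------------------------------------------
# dependency features
# ---------------------------------------------------------------------------

class TestDependencyFeatures:
    def _toy(self):
        rng = np.random.default_rng(0)
        dep = pd.DataFrame(rng.normal(size=(3, 30)), index=list("ABC"),
                           columns=[f"CL{i}" for i in range(30)])
        mut = pd.DataFrame(rng.integers(0, 2, size=(3, 30)), index=list("ABC"),
                           columns=dep.columns)
        return dep, mut

    def test_degenerate_split_keeps_average(self):
        dep, mut = self._toy()
        mut.loc[:] = 0
        out = dependency_features(("A", "B"), dep, mut)
        assert np.isnan(out["dep_stat"]) and np.isnan(out["dep_pvalue"])
        assert np.isfinite(out["avg"])

    def test_identical_profiles_give_perfect_correlation(self):
        dep, mut = self._toy()
        dep.loc["B"] = dep.loc["A"]
        out = dependency_features(("A", "B"), dep, mut)
        assert out["cor_stat"] == pytest.approx(1.0)
        assert out["cor_pvalue"] == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        dep, mut = self._toy()
        assert dependency_features(("A", "B"), dep, mut) == dependency_features(("B", "A"), dep, mut)

    def test_missing_gene_raises(self):
        dep, mut = self._toy()
        with pytest.raises(KeyError):
            dependency_features(("A", "Z"), dep, mut)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

class TestCox:
    def _simulate(self, n=600, beta=(0.7, 0.0, 0.0, 0.0), seed=0, censor=0.2):
        rng = np.random.default_rng(seed)
        X = np.column_stack([
            rng.integers(0, 2, n),
            rng.integers(0, 2, n),
            rng.uniform(30, 85, n),
            rng.choice(3, n),
        ]).astype(float)
        h = 0.001 * np.exp(X @ np.array(beta))
        t = rng.exponential(1 / h)
        c = rng.exponential(1 / (0.001 * censor / (1 - censor)), n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        return X, time, event

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        X, time, event = self._simulate(n=400, seed=3)
        beta, cov, ll, conv = cox_partial_likelihood_fit(X, time, event)
        assert conv
        df = pd.DataFrame(X, columns=["s", "sex", "age", "race"])
        df["T"] = time
        df["E"] = event
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(np.sqrt(cov[0, 0]), cph.standard_errors_.iloc[0], atol=1e-4)

    def test_recovers_log_hazard_ratio(self):
        X, time, event = self._simulate(n=1500, beta=(np.log(2), 0, 0, 0), seed=5)
        beta, cov, _, conv = cox_partial_likelihood_fit(X, time, event)
        assert conv
        assert abs(beta[0] - np.log(2)) < 0.15

    def test_constant_alteration_is_missing(self, null_small):
        _, labels, bundle = null_small
        alt = alteration_matrix(bundle, mode="survival")
        alt.loc[:, :] = 0
        assert cox_survival_feature(labels.pairs[0], bundle, alt=alt) is None

    def test_null_wald_p_uniform(self):
        ps = []
        for seed in range(120):
            X, time, event = self._simulate(n=150, beta=(0, 0, 0, 0), seed=seed)
            fit = cox_partial_likelihood_fit(X, time, event)
            if fit is None or not fit[3]:
                continue
            beta, cov, _, _ = fit
            z = beta[0] / np.sqrt(cov[0, 0])
            ps.append(2 * stats.norm.sf(abs(z)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

class TestExpression:
    def test_pearson_three_points(self):
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 2]], index=["A", "B"], columns=list("xyz"))
        corr, p = coexpression_features(("A", "B"), expr)
        assert corr == pytest.approx(np.sqrt(3) / 2, abs=1e-3)
        r = np.sqrt(3) / 2
        t = r * np.sqrt(1) / np.sqrt(1 - r ** 2)
        assert p == pytest.approx(2 * stats.t.sf(t, df=1), abs=1e-9)

    def test_collinear_and_degenerate(self):
        expr = pd.DataFrame([[1.0, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 5]],
                            index=["A", "B", "C"], columns=list("wxyz"))
        corr, p = coexpression_features(("A", "B"), expr)
        assert corr == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(coexpression_features(("A", "C"), expr)[0])
        assert np.isnan(coexpression_features(("A", "B"), None)[0])

    def test_tmm_identical_and_scaled_columns(self):
        rng = np.random.default_rng(0)
        base = rng.negative_binomial(5, 0.1, size=200)
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)

    def test_tmm_null_factors_near_one(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(4, 1, size=500))
        counts = pd.DataFrame(
            {f"s{j}": rng.negative_binomial(5, 5 / (5 + mu)).astype(int) for j in range(8)}
        )
        f = tmm_factors(counts)
        assert ((f > 0.9) & (f < 1.1)).all()

    def test_tmm_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="zero library"):
            tmm_factors(counts)

    def test_nb_exact_test_null_calibration(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(400):
            mu, phi, n1, n0 = 50.0, 0.15, 12, 28
            r = 1 / phi
            s1 = rng.negative_binomial(n1 * r, (n1 * r) / (n1 * r + n1 * mu))
            s0 = rng.negative_binomial(n0 * r, (n0 * r) / (n0 * r + n0 * mu))
            ps.append(nb_exact_test(s1, n1, s0, n0, phi))
        # doubled-tail discrete p: conservative but not degenerate
        ps = np.asarray(ps)
        assert ps.min() >= 0 and ps.max() <= 1
        assert 0.4 < ps.mean() < 0.65

    def test_all_zero_gene_missing(self, null_small):
        import copy

        _, labels, bundle = null_small
        b2 = copy.copy(bundle)
        counts = bundle.tumour_counts.copy()
        a, b = labels.pairs[0]
        counts.loc[a] = 0
        counts.loc[b] = 0
        b2.tumour_counts = counts
        from sbsl.features import diff_expression_features

        out = diff_expression_features((a, b), b2)
        assert np.isnan(out["diff_exp_pvalue"])


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

class TestPathways:
    def test_no_common_pathway_gives_zero(self):
        pw = {"P1": {"A", "X"}, "P2": {"B", "Y"}, "P3": {"C"}}
        assert pathway_coparticipation(("A", "B"), pw) == 0.0

    def test_shares_hypergeom_arithmetic(self):
        # nT=10, nA=4, nB=5, nAB=2 as pathway-membership counts
        pw = {}
        for i in range(10):
            pw[f"P{i}"] = set()
        for i in range(4):
            pw[f"P{i}"].add("A")
        for i in [0, 1, 4, 5, 6]:
            pw[f"P{i}"].add("B")
        assert pathway_coparticipation(("A", "B"), pw) == pytest.approx(66 / 252)

    def test_absent_gene_missing_and_empty_collection_rejected(self):
        pw = {"P1": {"A", "B"}, "P2": {"A"}, "P3": {"B"}}
        assert np.isnan(pathway_coparticipation(("A", "Z"), pw))
        with pytest.raises(ValueError):
            pathway_coparticipation(("A", "B"), {})
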