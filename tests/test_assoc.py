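"""PCA, association, inflation, PVE, Moran's I, stratification, HE."""

import numpy as np
import pytest
from scipy import stats

from spc.assoc_eval import (
    CHI2_1_MEDIAN,
    CovariateSet,
    coordinate_r2,
    deme_means,
    genomic_inflation,
    genotype_pca,
    gwas_linear,
    he_heritability,
    make_grm,
    morans_i,
    pve,
    rook_weights,
    stratified_pvalue_comparison,
)

from conftest import make_genotypes


def covset(mat, kind="custom"):
    mat = np.asarray(mat, float)
    return CovariateSet(samples=None, matrix=mat,
                        labels=[f"C{i}" for i in range(mat.shape[1])], kind=kind)


class TestGenotypePCA:
    def test_two_populations_separated_by_pc1(self):
        rng = np.random.default_rng(0)
        n = 60
        pop = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        freqs = np.column_stack([rng.uniform(0.1, 0.4, 80),
                                 rng.uniform(0.6, 0.9, 80)])
        d = rng.binomial(2, freqs[:, pop].T).astype(np.int8)
        pcs = genotype_pca(make_genotypes(d), k=2)
        signs = np.sign(pcs.matrix[:, 0])
        assert abs(signs[pop == 0].sum()) == n // 2
        assert abs(signs[pop == 1].sum()) == n // 2
        assert (signs[pop == 0][0] != signs[pop == 1][0])

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        g = make_genotypes(d)
        k = 8
        pcs = genotype_pca(g, k=k)
        p = g.allele_freqs
        keep = (p > 0) & (p < 1)
        Z = (d[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        U, S, _ = np.linalg.svd(Z, full_matrices=False)
        for j in range(k):  # compare up to sign, skipping degenerate pairs
            if j + 1 < len(S) and abs(S[j] - S[j + 1]) < 1e-8 * S[0]:
                continue
            np.testing.assert_allclose(
                np.abs(pcs.matrix[:, j]), np.abs(U[:, j]), atol=1e-8
            )

    def test_duplicating_samples_duplicates_scores(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(20, 30)).astype(np.int8)
        g1 = make_genotypes(d)
        g2 = make_genotypes(np.vstack([d, d]),
                            sample_ids=[f"s{i}" for i in range(40)])
        p1 = genotype_pca(g1, k=2).matrix
        p2 = genotype_pca(g2, k=2).matrix
        # duplicated cohort: each sample's coordinate appears twice (and the
        # unit-norm vector rescales by 1/sqrt(2))
        np.testing.assert_allclose(
            np.abs(p2[:20]) * np.sqrt(2), np.abs(p1), atol=1e-8
        )
        np.testing.assert_allclose(p2[:20], p2[20:], atol=1e-10)

    def test_monomorphic_excluded(self):
        d = np.column_stack([np.zeros(30, np.int8),
                             np.random.default_rng(1).integers(0, 3, 30),
                             np.full(30, 2, np.int8)])
        pcs = genotype_pca(make_genotypes(d.astype(np.int8)), k=1)
        assert np.isfinite(pcs.matrix).all()


class TestPVE:
    def test_self_covariate_explains_everything(self):
        y = np.random.default_rng(0).standard_normal(200)
        r = pve(y, covset(y[:, None]))
        assert r.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noise_covariates_sit_at_chance_level(self):
        rng = np.random.default_rng(1)
        n, c = 1000, 25
        y = rng.standard_normal(n)
        r = pve(y, covset(rng.standard_normal((n, c))))
        assert r.r2 == pytest.approx(c / n, abs=0.02)
        assert r.r2_adjusted == pytest.approx(0.0, abs=0.02)

    def test_deme_onehot_recovers_between_deme_fraction(self):
        rng = np.random.default_rng(2)
        per, R = 400, 5
        rows = np.repeat(np.arange(R), per)
        sigma = 1.0
        means = 2.0 * sigma * (R - 1 - rows) / (R - 1)
        y = rng.normal(means, sigma)
        onehot = (rows[:, None] == np.arange(R - 1)[None, :]).astype(float)
        expected = means.var() / (means.var() + sigma**2)
        r = pve(y, covset(onehot))
        assert r.r2 == pytest.approx(expected, abs=0.03)

    def test_invariant_to_invertible_remixing(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(300)
        X = rng.standard_normal((300, 6))
        M = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        assert pve(y, covset(X)).r2 == pytest.approx(pve(y, covset(X @ M)).r2,
                                                     abs=1e-10)

    def test_coordinate_r2_onehot_perfect_random_chance(self):
        rng = np.random.default_rng(4)
        labels = np.column_stack([rng.integers(0, 4, 800), rng.integers(0, 4, 800)])
        deme = labels[:, 0] * 4 + labels[:, 1]
        onehot = (deme[:, None] == np.arange(15)[None, :]).astype(float)
        rv, rh = coordinate_r2(covset(onehot), labels)
        assert rv == pytest.approx(1.0, abs=1e-10)
        assert rh == pytest.approx(1.0, abs=1e-10)
        c = 20
        rv, rh = coordinate_r2(covset(rng.standard_normal((800, c))), labels)
        assert rv < 3 * c / 800 and rh < 3 * c / 800


class TestGWAS:
    def test_phenotype_as_fake_variant(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(300, 5)).astype(np.int8)
        y = d[:, 2].astype(float)
        res = gwas_linear(make_genotypes(d), y)
        row = res.table.iloc[2]
        assert row["beta"] == pytest.approx(1.0, abs=1e-9)
        assert row["p"] == 1e-300

    def test_matches_full_multiple_regression_oracle(self):
        rng = np.random.default_rng(1)
        n, m, c = 150, 100, 4
        d = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(np.int8)
        cov = rng.standard_normal((n, c))
        y = rng.standard_normal(n) + cov @ rng.standard_normal(c) * 0.3
        res = gwas_linear(make_genotypes(d), y, covset(cov))
        for j in rng.choice(m, 25, replace=False):
            X = np.column_stack([np.ones(n), cov, d[:, j]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = n - X.shape[1]
            sigma2 = resid @ resid / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
            t = beta[-1] / se
            p = 2 * stats.t.sf(abs(t), dof)
            row = res.table.iloc[j]
            assert row["beta"] == pytest.approx(beta[-1], abs=1e-8)
            assert row["se"] == pytest.approx(se, rel=1e-8)
            assert row["p"] == pytest.approx(p, rel=1e-6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        n, m = 400, 5000
        d = rng.binomial(2, rng.uniform(0.05, 0.95, m), size=(n, m)).astype(np.int8)
        y = rng.standard_normal(n)
        res = gwas_linear(make_genotypes(d), y)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_flagged(self):
        d = np.column_stack([np.zeros(50, np.int8),
                             np.random.default_rng(3).integers(0, 3, 50)])
        res = gwas_linear(make_genotypes(d), np.random.default_rng(4).standard_normal(50))
        assert res.table["flag"].tolist()[0] == "monomorphic"
        assert res.table["p"].iloc[0] == 1.0 and res.table["beta"].iloc[0] == 0.0


class TestInflation:
    def test_reference_median_is_unity(self):
        est = genomic_inflation(np.full(500, CHI2_1_MEDIAN), n_boot=10)
        assert est.lambda_gc == pytest.approx(1.0)

    def test_scale_equivariance(self):
        chi = np.random.default_rng(0).chisquare(1, 2000)
        l1 = genomic_inflation(chi, n_boot=10).lambda_gc
        l2 = genomic_inflation(2 * chi, n_boot=10).lambda_gc
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_chi2_draws_calibrated_with_ci(self):
        chi = np.random.default_rng(1).chisquare(1, 10_000)
        est = genomic_inflation(chi, n_boot=500, seed=2)
        assert est.lambda_gc == pytest.approx(1.0, abs=0.03)
        assert est.ci_low <= 1.0 <= est.ci_high
        assert est.ci_low <= est.lambda_gc <= est.ci_high

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            genomic_inflation(np.ones(10))


class TestMoran:
    def chain_weights(self, n=4):
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        return W

    def test_chain_hand_oracle(self):
        # hand derivation: z = (-1.5,-.5,.5,1.5), sum_ij w z_i z_j = 2.5,
        # sum z^2 = 5, W = 6  ->  I = (4/6)(2.5/5) = 1/3
        res = morans_i(np.array([1.0, 2, 3, 4]), self.chain_weights())
        assert res.I == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_chain_row_standardized_matches_ape(self):
        # independent oracle: R ape::Moran.I(c(1,2,3,4), chain W) = 0.4
        W = self.chain_weights()
        W = W / W.sum(axis=1, keepdims=True)
        res = morans_i(np.array([1.0, 2, 3, 4]), W)
        assert res.I == pytest.approx(0.4, abs=1e-12)

    def test_checkerboard_perfect_negative(self):
        g = 4
        vals = np.array([(i + j) % 2 * 2 - 1 for i in range(g) for j in range(g)],
                        float)
        res = morans_i(vals, rook_weights(g))
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(16)
        W = rook_weights(4)
        sims = [morans_i(rng.permutation(x), W).I for _ in range(3000)]
        n = 16
        assert np.mean(sims) == pytest.approx(-1 / (n - 1), abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(5), np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="zero"):
            morans_i(np.arange(5.0), np.zeros((5, 5)))

    def test_deme_means_row_major(self):
        labels = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0, 0]])
        vals = np.array([1.0, 2.0, 3.0, 4.0, 3.0])
        np.testing.assert_allclose(deme_means(vals, labels, 2), [2, 2, 3, 4])


class TestStratified:
    def make_results(self, seed=0, m=60):
        rng = np.random.default_rng(seed)
        n = 120
        d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(np.int8)
        d[:, 1] = d[:, 0]  # perfect LD duplicate of causal 0
        g = make_genotypes(d, positions=np.arange(1, m + 1) * 500)
        y = d[:, 0] + rng.standard_normal(n)
        res = gwas_linear(g, y)
        return g, res

    def test_identical_results_give_wilcoxon_one(self):
        g, res = self.make_results()
        rep = stratified_pvalue_comparison(res, res, np.array([0]), g)
        for s in rep["strata"].values():
            if s is not None:
                assert s["wilcoxon_p"] == 1.0

    def test_empty_truth_means_all_non_causal(self):
        g, res = self.make_results()
        rep = stratified_pvalue_comparison(res, res, np.array([], dtype=int), g)
        assert rep["strata"]["causal"] is None and rep["strata"]["ld"] is None
        assert rep["strata"]["non_causal"]["n"] == g.n_variants

    def test_ld_promotion_and_strict_boundary(self):
        g, res = self.make_results()
        rep = stratified_pvalue_comparison(res, res, np.array([0]), g,
                                           ld_r2_threshold=0.1)
        assert rep["strata"]["ld"] is not None  # the duplicate variant
        # at threshold exactly 1.0 the duplicate (r2 == 1.0) stays non-causal
        rep2 = stratified_pvalue_comparison(res, res, np.array([0]), g,
                                            ld_r2_threshold=1.0)
        assert rep2["strata"]["ld"] is None


class TestHeritability:
    def test_single_variant_fully_genetic(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.5, size=(300, 1)).astype(np.int8)
        g = make_genotypes(d)
        z = (d[:, 0] - d[:, 0].mean()) / d[:, 0].std()
        est = he_heritability(g, z)
        # the GRM standardizes by 2p(1-p) while the phenotype is scaled by
        # the empirical variance; at n=300 the two differ by a few percent
        assert est["h2"] == pytest.approx(1.0, abs=0.1)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(1)
        n, m = 300, 400
        d = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(np.int8)
        y = rng.standard_normal(n)
        est = he_heritability(make_genotypes(d), y)
        assert abs(est["h2_raw"]) < max(2 * est["se"], 0.05)

    def test_recovers_simulated_h2(self):
        rng = np.random.default_rng(2)
        n, m = 800, 1200
        d = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(np.int8)
        g = make_genotypes(d)
        p = g.allele_freqs
        Z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        beta = rng.standard_normal(m) * np.sqrt(0.6 / m)
        score = Z @ beta
        y = score + rng.standard_normal(n) * np.sqrt(1 - score.var())
        est = he_heritability(g, y)
        assert est["h2"] == pytest.approx(0.6, abs=3 * est["se"] + 0.02)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="50"):
            he_heritability(np.eye(10), np.arange(10.0))

    def test_grm_diagonal_near_one(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 500), size=(100, 500)).astype(np.int8)
        K = make_grm(make_genotypes(d))
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)
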