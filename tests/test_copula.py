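"""Gene partitioning, distributional transform, correlation estimation."""

import numpy as np
import pytest
from scipy import stats

from copulacount.copula import (FitConfig, distributional_transform,
                                estimate_copula_correlation,
                                fit_cell_type_model, kendall_tau_matrix,
                                partition_genes, tau_plugin_correlation,
                                tau_to_copula_corr)
from copulacount.marginals import Family, FittedMarginal, PSI_INF, fit_poisson


def tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                c += 1
            else:
                d += 1
    denom = np.sqrt((c + d + tx) * (c + d + ty))
    return (c - d) / denom if denom > 0 else 0.0


class TestPartition:
    def test_dense_gene_goes_to_group1(self):
        X = np.vstack([np.ones(100, dtype=int), np.zeros(100, dtype=int)])
        part = partition_genes(X)
        assert 0 in part.group1 and 1 in part.group3

    def test_boundary_arithmetic(self):
        # n=10, 8 zeros: zero prop 0.8 (not < 0.8), expressed in 2 < 3 -> group3
        g_a = np.array([0] * 8 + [1, 2])
        # n=100, 80 zeros: zero prop 0.8, expressed in 20 >= 3 -> group2
        g_b = np.array([0] * 80 + [1] * 20)
        assert 0 in partition_genes(g_a[None, :]).group3
        assert 0 in partition_genes(g_b[None, :]).group2
        # 79 zeros: zero prop 0.79 < 0.8 -> group1
        g_c = np.array([0] * 79 + [1] * 21)
        assert 0 in partition_genes(g_c[None, :]).group1

    def test_groups_partition_all_genes(self, rng):
        X = rng.poisson(rng.uniform(0, 2, size=(30, 1)), size=(30, 50))
        part = partition_genes(X)
        combined = np.sort(np.concatenate(
            [part.group1, part.group2, part.group3]))
        assert np.array_equal(combined, np.arange(30))

    def test_group1_monotone_in_cutoff(self, rng):
        X = rng.poisson(rng.uniform(0, 3, size=(40, 1)), size=(40, 200))
        g1_strict = set(partition_genes(X, 0.5).group1.tolist())
        g1_loose = set(partition_genes(X, 0.8).group1.tolist())
        assert g1_strict <= g1_loose

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            partition_genes(np.zeros((3, 0), dtype=int))


class TestDistributionalTransform:
    def test_zero_count_forces_formula(self, rng):
        m = fit_poisson([0, 1, 2, 3])
        X = np.zeros((1, 4), dtype=int)
        scores = distributional_transform(X, [m], rng)
        from copulacount.marginals import marginal_cdf
        expected = (1 - scores.v_star[0]) * marginal_cdf(m, 0)
        np.testing.assert_allclose(scores.u_star[0], expected)

    def test_scores_strictly_inside_unit_interval(self, rng):
        m = FittedMarginal(Family.ZINB, 0.9, 0.5, 0.1, 0.0, 0)
        X = np.zeros((1, 1000), dtype=int)
        u = distributional_transform(X, [m], rng).u_star
        assert np.all((u > 0) & (u < 1))

    def test_uniformity_under_true_marginal(self):
        """KS uniformity holds for a correctly specified marginal."""
        m = FittedMarginal(Family.NB, 0.0, 2.0, 5.0, 0.0, 0)
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.negative_binomial(2.0, 2.0 / 7.0, size=800)
            u = distributional_transform(x[None, :], [m], rng).u_star[0]
            if stats.kstest(u, "uniform").pvalue > 0.01:
                passed += 1
        assert passed >= 18

    def test_mismatched_marginals_rejected(self, rng):
        with pytest.raises(ValueError):
            distributional_transform(np.zeros((2, 5), dtype=int),
                                     [fit_poisson([1, 2])], rng)


class TestCorrelationEstimation:
    def test_diagonal_is_exactly_one(self, rng):
        m = FittedMarginal(Family.POISSON, 0.0, PSI_INF, 5.0, 0.0, 0)
        X = rng.poisson(5.0, size=(4, 300))
        scores = distributional_transform(X, [m] * 4, rng)
        R = estimate_copula_correlation(scores)
        np.testing.assert_array_equal(np.diag(R), np.ones(4))
        np.testing.assert_allclose(R, R.T)

    def test_independent_genes_give_near_identity(self, rng):
        m = FittedMarginal(Family.POISSON, 0.0, PSI_INF, 5.0, 0.0, 0)
        X = rng.poisson(5.0, size=(5, 2000))
        R = estimate_copula_correlation(
            distributional_transform(X, [m] * 5, rng))
        off = R[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_bivariate_recovery(self):
        """True copula correlation 0.8 recovered within ±0.05 on average."""
        rho = 0.8
        m = FittedMarginal(Family.NB, 0.0, 2.0, 10.0, 0.0, 0)
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.multivariate_normal(
                [0, 0], [[1, rho], [rho, 1]], size=2000).T
            from copulacount.marginals import marginal_quantile
            u = np.clip(stats.norm.cdf(z), 0, 1 - 1e-16)
            X = np.vstack([marginal_quantile(m, u[0]),
                           marginal_quantile(m, u[1])])
            R = estimate_copula_correlation(
                distributional_transform(X, [m, m], rng))
            ests.append(R[0, 1])
        assert np.mean(ests) == pytest.approx(rho, abs=0.05)

    def test_rank_deficient_still_valid_correlation(self, rng):
        """More genes than cells: output must stay PSD with unit diagonal."""
        m = FittedMarginal(Family.POISSON, 0.0, PSI_INF, 8.0, 0.0, 0)
        X = rng.poisson(8.0, size=(12, 6))
        R = estimate_copula_correlation(
            distributional_transform(X, [m] * 12, rng))
        assert np.linalg.eigvalsh(R).min() >= -1e-8
        np.testing.assert_allclose(np.diag(R), 1.0)


class TestTauLink:
    def test_exact_values(self):
        assert tau_to_copula_corr(0.0) == 0.0
        assert tau_to_copula_corr(1.0) == pytest.approx(1.0)
        assert tau_to_copula_corr(-1.0) == pytest.approx(-1.0)
        assert tau_to_copula_corr(1.0 / 3.0) == pytest.approx(0.5)

    def test_odd_and_increasing(self):
        taus = np.linspace(-1, 1, 41)
        vals = tau_to_copula_corr(taus)
        np.testing.assert_allclose(vals, -tau_to_copula_corr(-taus))
        assert np.all(np.diff(vals) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tau_to_copula_corr(1.5)

    def test_tau_matrix_matches_bruteforce_oracle(self, rng):
        X = rng.poisson(2.0, size=(3, 40))
        T = kendall_tau_matrix(X)
        for h in range(3):
            for l in range(h + 1, 3):
                assert T[h, l] == pytest.approx(
                    tau_b_oracle(X[h], X[l]), abs=1e-12)

    def test_plugin_and_gaussian_routes_agree(self):
        """sin(pi*tau_b/2) tracks the Gaussian-scores estimate."""
        rho = 0.6
        m = FittedMarginal(Family.NB, 0.0, 3.0, 20.0, 0.0, 0)
        rng = np.random.default_rng(17)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000).T
        from copulacount.marginals import marginal_quantile
        u = np.clip(stats.norm.cdf(z), 0, 1 - 1e-16)
        X = np.vstack([marginal_quantile(m, u[0]), marginal_quantile(m, u[1])])
        plugin = tau_plugin_correlation(X)[0, 1]
        gauss = estimate_copula_correlation(
            distributional_transform(X, [m, m], rng))[0, 1]
        assert plugin == pytest.approx(gauss, abs=0.05)


class TestFitCellTypeModel:
    def test_all_zero_matrix(self, rng):
        X = np.zeros((5, 50), dtype=int)
        model = fit_cell_type_model(X, rng=rng)
        assert model.partition.group3.size == 5
        assert model.corr.shape == (0, 0)

    def test_partition_and_bookkeeping(self, small_counts, rng):
        X, _ = small_counts
        model = fit_cell_type_model(X, cell_type="t", rng=rng)
        assert model.n_cells == X.shape[1]
        assert model.total_count == X.sum()
        assert model.corr.shape == (model.partition.group1.size,) * 2
        assert set(model.marginals) == set(
            np.concatenate([model.partition.group1,
                            model.partition.group2]).tolist())

    def test_single_cell_falls_back_to_independent(self, rng):
        X = np.array([[4], [7]])
        with pytest.warns(UserWarning, match="fewer than 2 cells"):
            model = fit_cell_type_model(X, rng=rng)
        assert model.use_copula is False

    def test_tau_estimator_flag(self, small_counts, rng):
        X, _ = small_counts
        model = fit_cell_type_model(
            X, config=FitConfig(corr_estimator="tau"), rng=rng)
        assert np.linalg.eigvalsh(model.corr).min() >= -1e-8
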