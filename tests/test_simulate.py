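"""Tests for the synthetic generator and the two benchmark studies."""

import numpy as np
import pytest

from ccindex import (
    CCIError,
    SimulationConfig,
    add_gaussian_noise,
    add_outlier_rows,
    cci,
    concordance_index_r12,
    density,
    frobenius_deviation_ratio,
    make_correlated_matrix,
    make_interfering_modules,
    numerical_rank,
    row_pearson_matrix,
    run_noise_sweep,
    run_robustness_comparison,
    transform,
)


class TestGenerator:
    def test_all_pairwise_correlations_are_unit(self, correlated_50x100):
        R = np.abs(row_pearson_matrix(correlated_50x100))
        assert R.min() >= 1.0 - 1e-10

    def test_proposition_chain(self, correlated_50x100):
        """Perfect pairwise correlation forces rank(G)=2, rank(Ĝ)=1 and both
        concordance indices at 1."""
        G = correlated_50x100
        assert numerical_rank(G) == 2
        Gh = transform(G)
        assert numerical_rank(Gh) == 1
        res = cci(G)
        assert np.sum(res.singular_values**2) == pytest.approx(50, abs=1e-10)
        assert res.r12 == pytest.approx(1.0, abs=1e-10)
        assert res.cci == pytest.approx(1.0, abs=1e-10)
        assert density(G) == pytest.approx(1.0, abs=1e-10)

    def test_first_row_is_uniform_base(self, rng):
        G = make_correlated_matrix(5, 1000, rng)
        assert 0.0 <= G[0].min() and G[0].max() <= 1.0
        assert abs(G[0].mean() - 0.5) < 0.05

    def test_rejects_tiny_shapes(self, rng):
        with pytest.raises(CCIError):
            make_correlated_matrix(1, 10, rng)


class TestNoise:
    def test_zero_sigma_identity(self, rng):
        X = rng.uniform(size=(5, 10))
        np.testing.assert_array_equal(add_gaussian_noise(X, 0.0, rng), X)

    def test_noise_moments(self, rng):
        X = np.zeros((200, 200))
        Y = add_gaussian_noise(X, 0.1, rng)
        assert abs((Y - X).std() - 0.1) < 0.005
        assert abs((Y - X).mean()) < 0.005

    def test_reproducible(self):
        X = np.zeros((4, 6))
        a = add_gaussian_noise(X, 0.3, np.random.default_rng(11))
        b = add_gaussian_noise(X, 0.3, np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)


class TestFrobeniusRatio:
    def test_identical_matrices(self, rng):
        X = rng.uniform(size=(6, 12))
        assert frobenius_deviation_ratio(X, X) == 0.0

    def test_negated_matrix_gives_two(self, rng):
        X = rng.uniform(size=(6, 12))
        assert frobenius_deviation_ratio(-X, X) == pytest.approx(2.0, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        A, B = rng.uniform(size=(5, 9)), rng.uniform(size=(5, 9))
        Ah, Bh = transform(A), transform(B)
        expected = np.sqrt(((Ah - Bh) ** 2).sum()) / np.sqrt((Bh**2).sum())
        assert frobenius_deviation_ratio(A, B) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(CCIError):
            frobenius_deviation_ratio(rng.uniform(size=(3, 5)), rng.uniform(size=(4, 5)))


class TestOutliers:
    def test_zero_outliers_unchanged(self, rng):
        X = rng.uniform(size=(5, 10))
        np.testing.assert_array_equal(add_outlier_rows(X, 0, rng), X)

    def test_row_count(self, correlated_50x100, rng):
        assert add_outlier_rows(correlated_50x100, 5, rng).shape == (55, 100)

    def test_outliers_uncorrelated_with_base(self, rng):
        cors = []
        for _ in range(50):
            G = make_correlated_matrix(3, 100, rng)
            Y = add_outlier_rows(G, 1, rng)
            cors.append(np.corrcoef(Y[0], Y[-1])[0, 1])
        assert abs(np.mean(cors)) < 0.1


class TestInterference:
    def test_no_interference_reduces_to_single_module(self, rng):
        X = make_interfering_modules(10, 0, 50, 0.0, rng)
        assert X.shape == (10, 50)
        assert cci(X).cci == pytest.approx(1.0, abs=1e-10)

    def test_two_noiseless_blocks_rank_at_most_four(self, rng):
        X = make_interfering_modules(10, 10, 50, 0.0, rng)
        assert numerical_rank(X) <= 4

    def test_combined_density_pair_bookkeeping(self, rng):
        """Combined density decomposes exactly over within- and cross-block pairs."""
        n1 = n2 = 8
        X = make_interfering_modules(n1, n2, 60, 0.0, rng)
        R = np.abs(row_pearson_matrix(X))
        iu = np.triu_indices(n1 + n2, k=1)
        total_pairs = (n1 + n2) * (n1 + n2 - 1) / 2
        within1 = np.abs(row_pearson_matrix(X[:n1]))[np.triu_indices(n1, k=1)].sum()
        within2 = np.abs(row_pearson_matrix(X[n1:]))[np.triu_indices(n2, k=1)].sum()
        cross = np.abs(row_pearson_matrix(X))[:n1, n1:].sum()
        assert density(X) == pytest.approx((within1 + within2 + cross) / total_pairs, abs=1e-10)
        # each noiseless block contributes all-unit within-pair weights
        assert within1 == pytest.approx(n1 * (n1 - 1) / 2, abs=1e-8)


class TestNoiseSweep:
    def test_table_shape_and_zero_sigma_column(self):
        cfg = SimulationConfig(n_rows=10, n_cols=30, n_reps=5, seed=1)
        table = run_noise_sweep(cfg, sigma_grid=(0.0, 0.1, 0.5))
        assert len(table) == 3 * 5
        at0 = table[table.sigma == 0.0]
        assert np.allclose(at0.cci, 1.0, atol=1e-10)
        assert np.allclose(at0.r_f, 0.0, atol=1e-10)

    def test_mean_cci_non_increasing_in_sigma(self):
        cfg = SimulationConfig(n_rows=20, n_cols=50, n_reps=30, seed=2)
        table = run_noise_sweep(cfg, sigma_grid=(0.01, 0.1, 0.3, 1.0))
        means = table.groupby("sigma")["cci"].mean()
        assert (np.diff(means.to_numpy()) <= 1e-9).all()


class TestRobustnessComparison:
    def test_level_zero_normalizes_to_one(self):
        cfg = SimulationConfig(n_rows=10, n_cols=30, n_reps=3, seed=3)
        table = run_robustness_comparison(cfg, scenario="outliers", level_grid=(0, 5),
                                          sigmas=(0.05,))
        at0 = table[table.level == 0]
        assert np.allclose(at0.cci_normalized, 1.0)
        assert np.allclose(at0.density_normalized, 1.0)

    def test_both_metrics_decline_with_outliers(self):
        cfg = SimulationConfig(n_rows=20, n_cols=50, n_reps=20, seed=4)
        table = run_robustness_comparison(cfg, scenario="outliers",
                                          level_grid=(0, 10, 20), sigmas=(0.05,))
        means = table.groupby("level")[["cci", "density"]].mean()
        assert (means["cci"].diff().dropna() < 0).all()
        assert (means["density"].diff().dropna() < 0).all()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(CCIError):
            run_robustness_comparison(SimulationConfig(n_reps=1), scenario="bogus")


class TestTwoConditionStudy:
    def test_planted_structure(self):
        from ccindex import cci, make_two_condition_study

        modules, expr_a, expr_b = make_two_condition_study(
            seed=1, n_modules_specific=2, n_modules_shared=1, module_size=10,
            n_background=30, n_samples=20, sigma=0.0)
        assert len(modules) == 3
        assert expr_a.shape == (3 * 10 + 30, 20)
        assert expr_a.gene_ids == expr_b.gene_ids
        # A-only block: perfectly concordant in A, noise-level in B
        sub_a, _ = expr_a.submatrix(modules[0])
        sub_b, _ = expr_b.submatrix(modules[0])
        assert cci(sub_a).cci > 1 - 1e-10
        assert cci(sub_b).cci < 0.6
        # shared block concordant in both
        sub_b2, _ = expr_b.submatrix(modules[2])
        assert cci(sub_b2).cci > 1 - 1e-10
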