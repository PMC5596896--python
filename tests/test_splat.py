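"""The simulation pipeline: each stage against its closed-form or Monte-Carlo
oracle, plus the whole-pipeline invariants (conservation, reproducibility,
mode equivalences)."""

import numpy as np
import pytest
from scipy import stats

import splatsim as ss
from splatsim.splat import (
    apply_expression_outliers,
    assign_cells,
    assign_path_positions,
    brownian_bridge,
    compute_cell_means,
    dropout_probability,
    simulate_base_means,
    simulate_batch_factors,
    simulate_bcv,
    simulate_counts,
    simulate_de_factors,
    simulate_dropout,
    simulate_library_sizes,
    simulate_path_factors,
    simulate_trended_means,
)


class TestBaseMeans:
    def test_empty_and_errors(self, rng):
        assert simulate_base_means(0, 2.0, 1.0, rng).size == 0
        with pytest.raises(ValueError):
            simulate_base_means(10, 0.0, 1.0, rng)
        with pytest.raises(ValueError):
            simulate_base_means(10, 1.0, -2.0, rng)

    def test_sample_mean_matches_gamma_expectation(self, rng):
        draws = simulate_base_means(10**6, 2.0, 1.0, rng)
        assert np.all(draws > 0)
        se = np.sqrt(2.0 / 10**6)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_distribution_matches_gamma_cdf(self, rng):
        draws = simulate_base_means(10**5, 3.0, 2.0, rng)
        pvalue = stats.kstest(draws, stats.gamma(3.0, scale=0.5).cdf).pvalue
        assert pvalue > 0.001


class TestExpressionOutliers:
    def test_no_outlier_limit(self, rng):
        means = np.array([1.0, 5.0, 9.0])
        out, flags, fac = apply_expression_outliers(means, 0.0, 4.0, 0.5, rng)
        assert np.array_equal(out, means)
        assert not flags.any()
        assert np.all(fac == 1.0)

    def test_degenerate_lognormal_all_outliers(self, rng):
        means = np.linspace(1, 10, 25)
        out, flags, _ = apply_expression_outliers(means, 1.0, 0.7, 0.0, rng)
        assert flags.all()
        assert np.allclose(out, np.median(means) * np.exp(0.7))

    def test_hand_computed_median_inflation(self, rng):
        means = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        out, _, _ = apply_expression_outliers(means, 1.0, np.log(2.0), 0.0, rng)
        assert np.allclose(out, 6.0)  # median 3 * factor 2

    def test_empty_input_is_an_error(self, rng):
        with pytest.raises(ValueError):
            apply_expression_outliers(np.array([]), 0.5, 1.0, 0.5, rng)


class TestLibrarySizes:
    def test_degenerate_scale_is_exact(self, rng):
        lib = simulate_library_sizes(50, 10.0, 0.0, rng)
        assert np.all(lib == np.exp(10.0))

    def test_log_mean_recovers_location(self, rng):
        lib = simulate_library_sizes(10**5, 10.0, 0.2, rng)
        se = 0.2 / np.sqrt(10**5)
        assert abs(np.log(lib).mean() - 10.0) < 3 * se

    def test_single_cell_and_errors(self, rng):
        assert simulate_library_sizes(1, 5.0, 0.1, rng).shape == (1,)
        with pytest.raises(ValueError):
            simulate_library_sizes(3, 5.0, -0.1, rng)


class TestDeFactors:
    def test_no_de_gives_all_ones(self, rng):
        fac = simulate_de_factors(200, 3, 0.0, 0.5, 0.1, 0.4, rng)
        assert fac.shape == (200, 3)
        assert np.all(fac == 1.0)

    def test_degenerate_factors(self, rng):
        fac = simulate_de_factors(500, 1, 1.0, 0.0, 0.3, 0.0, rng)
        assert np.allclose(fac, np.exp(0.3))

    def test_de_gene_count_is_binomial(self, rng):
        fac = simulate_de_factors(5000, 1, 0.1, 0.5, 0.1, 0.4, rng)
        n_de = int((fac != 1.0).sum())
        assert abs(n_de - 500) < 3 * np.sqrt(5000 * 0.1 * 0.9)

    def test_bad_probability_is_an_error(self, rng):
        with pytest.raises(ValueError):
            simulate_de_factors(10, 1, 1.5, 0.5, 0.1, 0.4, rng)


class TestAssignCells:
    def test_single_group(self, rng):
        groups, batches = assign_cells(7, [1.0], [7], rng)
        assert np.all(groups == 1) and np.all(batches == 1)

    def test_group_counts_match_probabilities(self, rng):
        groups, _ = assign_cells(400, [0.6, 0.25, 0.15], [400], rng)
        n1 = int((groups == 1).sum())
        assert abs(n1 - 240) < 3 * np.sqrt(400 * 0.6 * 0.4)

    def test_batch_blocks(self, rng):
        _, batches = assign_cells(5, [1.0], [3, 2], rng)
        assert batches.tolist() == [1, 1, 1, 2, 2]

    def test_inconsistent_batches_error(self, rng):
        with pytest.raises(ValueError):
            assign_cells(5, [1.0], [3, 3], rng)


class TestBatchFactors:
    def test_degenerate_scale(self, rng):
        fac = simulate_batch_factors(40, 2, 0.3, 0.0, rng)
        assert np.allclose(fac, np.exp(0.3))

    def test_identity_batch(self, rng):
        fac = simulate_batch_factors(40, 1, 0.0, 0.0, rng)
        assert np.all(fac == 1.0)

    def test_log_mean(self, rng):
        fac = simulate_batch_factors(10**5, 1, 0.1, 0.1, rng)
        se = 0.1 / np.sqrt(10**5)
        assert abs(np.log(fac).mean() - 0.1) < 3 * se


class TestCellMeans:
    def test_hand_arithmetic(self):
        out = compute_cell_means(np.array([[1.0], [1.0], [2.0]]), np.array([8.0]))
        assert np.allclose(out[:, 0], [2.0, 2.0, 4.0])

    def test_identity_when_sum_matches(self):
        col = np.array([[1.0], [3.0]])
        assert np.allclose(compute_cell_means(col, np.array([4.0])), col)

    def test_columns_sum_to_library_sizes(self, rng):
        m = rng.gamma(1.0, 2.0, size=(100, 7)) + 1e-9
        lib = rng.lognormal(8, 0.3, 7)
        out = compute_cell_means(m, lib)
        assert np.allclose(out.sum(axis=0), lib, rtol=1e-9)

    def test_zero_column_is_an_error(self):
        with pytest.raises(ValueError, match="column 1"):
            compute_cell_means(np.array([[1.0, 0.0], [1.0, 0.0]]), np.array([5.0, 5.0]))


class TestBcv:
    def test_large_df_concentrates_to_trend(self, rng):
        means = np.array([[1.0, 4.0, 100.0]])
        bcv = simulate_bcv(means, 0.2, 1e9, rng)
        expected = 0.2 + 1.0 / np.sqrt(means)
        assert np.allclose(bcv, expected, rtol=1e-3)

    def test_monotone_decreasing_in_mean(self, rng):
        means = np.array([[1.0, 10.0, 100.0, 1000.0]])
        bcv = simulate_bcv(means, 0.1, 10.0, rng)
        assert np.all(np.diff(bcv[0]) <= 0)

    def test_bad_df_is_an_error(self, rng):
        with pytest.raises(ValueError):
            simulate_bcv(np.array([[1.0]]), 0.1, 0.0, rng)


class TestTrendedMeans:
    def test_vanishing_cv_limit(self, rng):
        means = np.linspace(1, 50, 100).reshape(10, 10)
        lam = simulate_trended_means(means, np.full_like(means, 1e-6), rng)
        assert np.allclose(lam, means, rtol=1e-3)

    def test_moments_of_gamma_parameterization(self, rng):
        means = np.full((1, 10**6), 10.0)
        lam = simulate_trended_means(means, np.full_like(means, 0.5), rng)
        se_mean = 10.0 * 0.5 / np.sqrt(10**6)
        assert abs(lam.mean() - 10.0) < 3 * se_mean
        cv = lam.std() / lam.mean()
        assert abs(cv - 0.5) < 0.01 * 0.5
        assert np.all(lam > 0)


class TestCounts:
    def test_zero_rate_gives_zero(self, rng):
        assert simulate_counts(np.zeros((3, 3)), rng).sum() == 0

    def test_poisson_moments(self, rng):
        y = simulate_counts(np.full((1, 10**6), 5.0), rng)
        assert abs(y.mean() - 5.0) < 3 * np.sqrt(5.0 / 10**6)
        assert abs(y.var() - 5.0) < 0.03 * 5.0

    def test_negative_rate_is_an_error(self, rng):
        with pytest.raises(ValueError):
            simulate_counts(np.array([[-1.0]]), rng)


class TestDropout:
    def test_probability_is_half_at_midpoint(self):
        for k in (0.5, 1.0, 3.0, -2.0):
            assert dropout_probability(1.7, 1.7, k) == 0.5

    def test_flat_logistic_at_zero_shape(self):
        x = np.linspace(-5, 5, 11)
        assert np.all(dropout_probability(x, 0.0, 0.0) == 0.5)

    def test_logistic_value(self):
        p = dropout_probability(np.log(10.0), 0.0, 1.0)
        assert np.isclose(p, 1.0 / 11.0)

    def test_mask_semantics_and_gene_mode(self, rng):
        lam = rng.gamma(2.0, 2.0, size=(50, 30)) + 0.1
        pre = rng.poisson(lam)
        prob, mask, counts = simulate_dropout(lam, 0.0, 1.0, rng, counts_pre_dropout=pre)
        assert np.array_equal(counts, pre * mask)
        prob_g, _, _ = simulate_dropout(lam, 0.0, 1.0, rng, by="gene")
        # one probability per gene in gene mode
        assert np.all(prob_g == prob_g[:, [0]])
        with pytest.raises(ValueError):
            simulate_dropout(lam, 0.0, 1.0, rng, by="sample")


class TestPaths:
    def test_bridge_hits_endpoints_exactly(self, rng):
        b = brownian_bridge(37, 0.5, rng, start=1.25, end=-2.5)
        assert b[0] == 1.25 and b[-1] == -2.5

    def test_trajectory_endpoints_and_positivity(self, rng):
        start = rng.gamma(1.0, 1.0, 200) + 0.05
        end = rng.gamma(1.0, 1.0, 200) + 0.05
        traj = simulate_path_factors(start, end, 50, 1.0, 0.8, rng)
        assert np.allclose(traj[:, 0], start)
        assert np.allclose(traj[:, -1], end)
        assert np.all(np.isfinite(traj)) and np.all(traj > 0)

    def test_zero_sigma_reduces_to_linear_interpolation(self, rng):
        start = np.array([1.0, 2.0])
        end = np.array([4.0, 0.5])
        traj = simulate_path_factors(start, end, 10, 1.0, 0.0, rng)
        t = np.arange(11) / 10
        expected = np.exp(np.log(start)[:, None] + (np.log(end) - np.log(start))[:, None] * t)
        assert np.allclose(traj, expected)

    def test_nonpositive_factors_error(self, rng):
        with pytest.raises(ValueError):
            simulate_path_factors(np.array([0.0]), np.array([1.0]), 5, 0.5, 0.1, rng)

    def test_uniform_positions_at_half_skew(self, rng):
        labels = np.ones(10**5, dtype=int)
        steps, frac = assign_path_positions(10**5, labels, [0.5], [10], rng)
        # Beta(1, 1) positions: interior steps get ~1/10, the end bins ~1/20
        freq = np.bincount(steps, minlength=11) / 10**5
        se = np.sqrt(0.1 * 0.9 / 10**5)
        assert np.all(np.abs(freq[1:-1] - 0.1) < 4 * se)
        assert abs(frac.mean() - 0.5) < 3 * (1 / np.sqrt(12 * 10**5))

    def test_high_skew_concentrates_at_path_end(self, rng):
        labels = np.ones(10**4, dtype=int)
        _, frac = assign_path_positions(10**4, labels, [0.99], [10], rng)
        assert frac.mean() > 0.9

    def test_skew_bounds_checked(self, rng):
        with pytest.raises(ValueError):
            assign_path_positions(5, np.ones(5, dtype=int), [1.5], [10], rng)


def _result_invariants(r):
    assert np.array_equal(r.counts, r.counts_pre_dropout * r.dropout_mask)
    assert np.allclose(r.cell_means.sum(axis=0), r.library_sizes, rtol=1e-6)
    assert np.all(r.de_factors > 0) and np.all(r.batch_factors > 0)
    assert np.issubdtype(r.counts.dtype, np.integer) and r.counts.min() >= 0


class TestSplatSimulate:
    def test_dropout_switch_contract(self, small_splat_result):
        r = small_splat_result
        assert r.dropout_mask.all()
        assert np.array_equal(r.counts, r.counts_pre_dropout)

    @pytest.mark.parametrize("mode", ["single", "groups", "paths"])
    def test_invariants_hold_in_every_mode(self, mode):
        overrides = dict(n_genes=300, n_cells=60, seed=9, batch_cells=[40, 20])
        if mode in ("groups", "paths"):
            overrides.update(group_probs=[0.5, 0.5], de_prob=[0.2, 0.2],
                             de_down_prob=[0.5, 0.5], de_loc=[0.3, 0.3],
                             de_scale=[0.4, 0.4])
        if mode == "paths":
            overrides.update(path_from=[0, 1], path_n_steps=[20, 30],
                             path_skew=[0.5, 0.5])
        p = ss.update_params(ss.default_params("splat"), overrides)
        r = ss.splat_simulate(p, mode=mode)
        _result_invariants(r)
        assert set(r.cell_meta.columns) >= {"cell_id", "group", "batch", "path", "step"}
        if mode == "paths":
            assert r.cell_meta["step"].max() <= 30

    def test_dropout_mode_invariants(self):
        p = ss.update_params(
            ss.default_params("splat"),
            dict(n_genes=300, n_cells=50, seed=5, batch_cells=[50],
                 dropout_present=True),
        )
        r = ss.splat_simulate(p)
        _result_invariants(r)
        assert not r.dropout_mask.all()  # some counts were zeroed

    def test_same_seed_bit_identical(self):
        p = ss.update_params(ss.default_params("splat"),
                             dict(n_genes=200, n_cells=30, seed=7, batch_cells=[30]))
        a, b = ss.splat_simulate(p), ss.splat_simulate(p)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.trended_means, b.trended_means)

    def test_trivial_groups_mode_equals_single_mode(self):
        p = ss.update_params(ss.default_params("splat"),
                             dict(n_genes=200, n_cells=30, seed=3, batch_cells=[30],
                                  de_prob=[0.0]))
        single = ss.splat_simulate(p, mode="single")
        grouped = ss.splat_simulate(p, mode="groups")
        assert np.array_equal(single.counts, grouped.counts)

    def test_trivial_groups_distribution_across_seeds(self):
        # cross-seed sanity: summaries from both modes share one distribution
        totals_single, totals_grouped = [], []
        for seed in range(10):
            p = ss.update_params(
                ss.default_params("splat"),
                dict(n_genes=150, n_cells=25, seed=100 + seed, batch_cells=[25],
                     de_prob=[0.0]))
            totals_single.append(ss.splat_simulate(p, "single").counts.sum())
            q = ss.update_params(p, dict(seed=200 + seed))
            totals_grouped.append(ss.splat_simulate(q, "groups").counts.sum())
        assert stats.ks_2samp(totals_single, totals_grouped).pvalue > 0.001

    def test_invalid_params_and_mode_rejected(self):
        p = ss.update_params(ss.default_params("splat"), dict(mean_shape=-1.0))
        with pytest.raises(ValueError, match="mean_shape"):
            ss.splat_simulate(p)
        with pytest.raises(ValueError, match="mode"):
            ss.splat_simulate(ss.default_params("splat"), mode="bulk")

    def test_gene_draws_stable_when_cells_added(self):
        base = dict(n_genes=100, seed=11)
        p1 = ss.update_params(ss.default_params("splat"),
                              dict(**base, n_cells=20, batch_cells=[20]))
        p2 = ss.update_params(ss.default_params("splat"),
                              dict(**base, n_cells=40, batch_cells=[40]))
        r1, r2 = ss.splat_simulate(p1), ss.splat_simulate(p2)
        assert np.array_equal(r1.base_means, r2.base_means)
        assert np.array_equal(r1.outlier_flags, r2.outlier_flags)
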