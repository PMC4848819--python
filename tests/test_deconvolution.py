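import numpy as np
import pytest

from pooldeconv import (
    CountMatrix,
    SimulationConfig,
    build_system,
    compute_sum_factors,
    define_pools,
    pool_factor,
    ring_order,
    simulate_counts,
    solve_factors,
)
from pooldeconv.deconvolution import Pool, PoolSystem
from .oracles import nnls_oracle, pool_factor_oracle, wls_oracle


class TestRingOrder:
    def test_six_cell_enumeration(self):
        """Largest first, evens descending in size, smallest at the antipode, odds back up."""
        sizes = np.array([60, 50, 40, 30, 20, 10])  # cells A..F, rank = index + 1
        seq = ring_order(sizes).sequence
        assert seq.tolist() == [0, 1, 3, 5, 4, 2]  # A, B, D, F, E, C

    def test_single_cell(self):
        assert ring_order(np.array([5.0])).sequence.tolist() == [0]

    def test_ties_broken_by_input_order(self):
        sizes = np.array([10, 10, 10, 10])
        a = ring_order(sizes).sequence
        b = ring_order(sizes).sequence
        assert a.tolist() == b.tolist() == [0, 1, 3, 2]


class TestDefinePools:
    def test_window_two_on_four_cells(self):
        ring = ring_order(np.array([4.0, 3.0, 2.0, 1.0]))
        pools = define_pools(ring, (2,))
        assert len(pools) == 4
        members = [set(p.members) for p in pools]
        seq = ring.sequence.tolist()
        expected = [{seq[i], seq[(i + 1) % 4]} for i in range(4)]
        assert members == expected
        counts_per_cell = np.bincount([c for p in pools for c in p.members])
        assert (counts_per_cell == 2).all()

    def test_window_equal_to_n(self):
        ring = ring_order(np.arange(1.0, 6.0))
        pools = define_pools(ring, (5,))
        assert all(set(p.members) == set(range(5)) for p in pools)

    def test_default_windows_on_200_cells_give_300_memberships(self):
        ring = ring_order(np.arange(200.0) + 1)
        pools = define_pools(ring)
        counts_per_cell = np.bincount([c for p in pools for c in p.members])
        assert (counts_per_cell == 300).all()
        assert len(pools) == 5 * 200

    def test_oversized_window_dropped_with_warning(self):
        ring = ring_order(np.arange(10.0) + 1)
        with pytest.warns(UserWarning, match="dropped"):
            pools = define_pools(ring, (5, 50))
        assert {p.window_size for p in pools} == {5}

    def test_error_when_no_window_fits(self):
        ring = ring_order(np.arange(3.0) + 1)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                define_pools(ring, (10, 20))


class TestPoolFactor:
    def test_identical_cells_give_window_size(self):
        profile = np.array([5, 2, 9, 1, 4])
        values = np.tile(profile[:, None], (1, 6))
        counts = CountMatrix(values)
        t = counts.library_sizes().astype(float)
        u = (values / t).mean(axis=1)
        pool = Pool((0, 2, 3), 3)
        assert pool_factor(counts, pool, t, u) == pytest.approx(3.0)

    def test_five_gene_toy_matches_oracle(self, small_counts):
        t = small_counts.library_sizes().astype(float)
        u = (small_counts.values / t).mean(axis=1)
        pool = Pool((1, 4, 7, 9), 4)
        got = pool_factor(small_counts, pool, t, u)
        want = pool_factor_oracle(small_counts.values, pool.members, t, u)
        assert got == pytest.approx(want, rel=1e-12)

    def test_linearity_in_pooled_counts(self):
        r = np.random.default_rng(2)
        values = r.integers(0, 40, size=(25, 8))
        values[0] += 1  # keep the reference positive somewhere
        counts = CountMatrix(values)
        t = counts.library_sizes().astype(float)
        u = (values / t).mean(axis=1)
        pool = Pool((0, 3, 5), 3)
        base = pool_factor(counts, pool, t, u)
        doubled = values.copy()
        doubled[:, [0, 3, 5]] *= 2
        # keep t and u fixed: doubling the pooled counts doubles the factor
        got = pool_factor(CountMatrix(doubled), pool, t, u)
        assert got == pytest.approx(2 * base, rel=1e-12)

    def test_median_robust_to_minority_contamination(self):
        """Corrupting fewer than half the genes moves the pool factor boundedly."""
        r = np.random.default_rng(4)
        values = r.integers(1, 50, size=(40, 10))
        counts = CountMatrix(values)
        t = counts.library_sizes().astype(float)
        u = (values / t).mean(axis=1)
        pool = Pool((0, 1, 2, 3), 4)
        clean = pool_factor(counts, pool, t, u)
        corrupted = values.copy()
        corrupted[:16, [0, 1, 2, 3]] *= 1000  # 40% of genes blown up
        got = pool_factor(CountMatrix(corrupted), pool, t, u)
        ratios = (values[:, list(pool.members)] / t[list(pool.members)]).sum(axis=1) / u
        assert got <= np.quantile(ratios, 0.95)
        assert got >= clean


class TestBuildSystem:
    def test_row_counts(self, rng):
        values = rng.poisson(8, size=(60, 50)) + 1
        system = build_system(CountMatrix(values), window_sizes=(10, 20))
        assert len(system.pools) == 100  # one pool per cell per window size
        a, b, w = system.design()
        assert a.shape == (150, 50)  # 100 pool rows + 50 anchor rows
        assert np.linalg.matrix_rank(a.toarray()) == 50
        assert (w[:100] == 1.0).all() and (w[100:] == system.low_weight).all()

    def test_adjustment_is_library_size(self, rng):
        values = rng.poisson(8, size=(30, 25)) + 1
        counts = CountMatrix(values)
        system = build_system(counts, window_sizes=(5,))
        assert np.array_equal(system.adjustment, counts.library_sizes().astype(float))
        z = values / system.adjustment
        assert np.allclose(system.reference_profile, z.mean(axis=1))


class TestSolveFactors:
    def test_exact_recovery_on_consistent_system(self, proportional_counts):
        counts, theta = proportional_counts
        res = compute_sum_factors(counts, window_sizes=(5, 10, 20))
        truth = theta / theta.mean()
        assert np.max(np.abs(res.factors.factor / truth - 1)) < 1e-8
        assert res.n_zero_factors == 0

    def test_identical_cells_give_unit_factors_and_equal_ses(self):
        profile = np.array([5, 2, 9, 1, 4, 11])
        values = np.tile(profile[:, None], (1, 12))
        res = compute_sum_factors(CountMatrix(values), window_sizes=(3, 4))
        assert np.allclose(res.factors.factor, 1.0)
        se = res.factors.std_error
        assert se is not None and np.allclose(se, se[0])

    def test_matches_dense_wls_oracle(self, rng):
        values = rng.poisson(6, size=(40, 12)) + 1
        counts = CountMatrix(values)
        system = build_system(counts, window_sizes=(3, 4))
        res = solve_factors(system, center=False)
        sol = wls_oracle(
            [p.members for p in system.pools],
            [p.factor_estimate for p in system.pools],
            system.anchor_estimates,
            system.low_weight,
            12,
        )
        assert np.allclose(res.factors.factor, sol * system.adjustment, rtol=1e-6)

    def test_negative_solution_resolved_by_constrained_solve(self):
        """A crafted system whose unconstrained solution is negative gets clamped at 0."""
        pools = [Pool((0, 1), 2, 1.0), Pool((1, 2), 2, 1.0), Pool((0, 2), 2, 2.5)]
        anchors = np.array([1.0, 1.0, 1.0])
        system = PoolSystem(pools, anchors, np.ones(3), np.ones(5))
        unconstrained = wls_oracle(
            [p.members for p in pools], [p.factor_estimate for p in pools],
            anchors, system.low_weight, 3,
        )
        assert unconstrained.min() < 0  # the instance really is problematic
        res = solve_factors(system, center=False)
        want = nnls_oracle(
            [p.members for p in pools], [p.factor_estimate for p in pools],
            anchors, system.low_weight, 3,
        )
        assert res.n_zero_factors >= 1
        assert np.allclose(res.factors.factor, want, atol=1e-6)


class TestComputeSumFactors:
    def test_single_cluster_equals_direct_call(self, rng):
        values = rng.poisson(6, size=(50, 30)) + 1
        counts = CountMatrix(values)
        direct = compute_sum_factors(counts, window_sizes=(5, 10))
        clustered = compute_sum_factors(
            counts, window_sizes=(5, 10), clusters=np.zeros(30, dtype=int)
        )
        assert np.allclose(direct.factors.factor, clustered.factors.factor, rtol=1e-9)

    def test_deterministic(self, rng):
        values = rng.poisson(6, size=(50, 30)) + 1
        counts = CountMatrix(values)
        a = compute_sum_factors(counts, window_sizes=(5, 10))
        b = compute_sum_factors(counts, window_sizes=(5, 10))
        assert np.array_equal(a.factors.factor, b.factors.factor)
        c = compute_sum_factors(counts, window_sizes=(5, 10), pool_strategy="random", seed=3)
        d = compute_sum_factors(counts, window_sizes=(5, 10), pool_strategy="random", seed=3)
        assert np.array_equal(c.factors.factor, d.factors.factor)

    def test_depth_invariance_on_zero_free_data(self, proportional_counts):
        counts, _ = proportional_counts
        scaled = counts.values.copy()
        scaled[:, 7] *= 5
        a = compute_sum_factors(counts, window_sizes=(5, 10)).factors.factor
        b = compute_sum_factors(CountMatrix(scaled), window_sizes=(5, 10)).factors.factor
        assert (b[7] / b[0]) / (a[7] / a[0]) == pytest.approx(5.0, rel=1e-7)

    def test_small_cluster_rejected(self, rng):
        values = rng.poisson(6, size=(40, 30)) + 1
        labels = np.array([0] * 25 + [1] * 5)
        with pytest.raises(ValueError, match="cluster"):
            compute_sum_factors(CountMatrix(values), window_sizes=(10, 20), clusters=labels)

    def test_ring_pools_beat_random_pools_on_average(self):
        """Pooling cells of similar library size improves precision over random pools."""
        rmse = {"ring": [], "random": []}
        for seed in range(20):
            cfg = SimulationConfig(n_genes=1000, subpop_sizes=(60, 60), seed=seed,
                                   up_fraction=(0.5, 0.5), up_fold=(5.0, 5.0))
            d = simulate_counts(cfg)
            for strategy in rmse:
                res = compute_sum_factors(
                    d.counts, window_sizes=(20, 40, 60),
                    pool_strategy=strategy, seed=seed + 1,
                )
                f = res.factors.factor
                f = f * d.true_bias.mean() / f.mean()
                rmse[strategy].append(np.sqrt(np.mean(np.log(f / d.true_bias) ** 2)))
        assert np.mean(rmse["ring"]) <= np.mean(rmse["random"])
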