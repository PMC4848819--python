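import numpy as np
import pytest

from pooldeconv import (
    CountMatrix,
    SimulationConfig,
    SizeFactorSet,
    benchmark,
    distance_to_median,
    filter_low_abundance,
    library_size_factors,
    offset_covariate_assessment,
    simulate_counts,
    summarize_reports,
)
from .oracles import running_median_oracle


class TestBenchmark:
    def setup_method(self):
        self.cfg = SimulationConfig(n_genes=400, subpop_sizes=(30, 30),
                                    up_fraction=(0.5, 0.5), up_fold=(5.0, 5.0))

    def test_truth_as_method_gives_zero_error(self, monkeypatch):
        # intercept the simulation so the "method" can return the true biases
        truth_store = {}

        def capture(counts):
            return SizeFactorSet(truth_store["theta"])

        import pooldeconv.evaluation as ev
        orig = ev.simulate_counts

        def wrapped(cfg):
            d = orig(cfg)
            truth_store["theta"] = d.true_bias
            return d

        monkeypatch.setattr(ev, "simulate_counts", wrapped)
        reports = benchmark(self.cfg, {"truth": capture}, seeds=[5])
        assert np.allclose(reports[0].log_errors, 0.0, atol=1e-12)

    def test_errors_invariant_to_global_rescaling(self):
        scaled = {
            "raw": library_size_factors,
            "x17": lambda c: SizeFactorSet(17.0 * library_size_factors(c).factor),
        }
        reports = benchmark(self.cfg, scaled, seeds=[2])
        assert np.allclose(reports[0].log_errors, reports[1].log_errors, atol=1e-12)

    def test_method_failure_recorded_not_fatal(self):
        def broken(counts):
            raise ValueError("boom")

        reports = benchmark(self.cfg, {"broken": broken, "ok": library_size_factors}, seeds=[1])
        assert reports[0].failed and not reports[1].failed
        summary = summarize_reports(reports)
        assert summary["method"].tolist() == ["ok"]


class TestOffsetCovariate:
    def _simulate(self, seed=11):
        cfg = SimulationConfig(n_genes=250, subpop_sizes=(80,), up_fraction=(0.5,),
                               up_fold=(5.0,), seed=seed)
        return simulate_counts(cfg)

    def test_true_offsets_yield_few_rejections(self):
        d = self._simulate()
        noise = SizeFactorSet(2.0 ** np.random.default_rng(0).normal(0, 0.5, 80))
        out = offset_covariate_assessment(
            d.counts, SizeFactorSet(d.true_bias), noise, fdr=0.05
        )
        assert out["n_tested"] > 200
        assert out["n_rejected"] / out["n_tested"] < 0.05

    def test_missing_normalization_is_detected_and_swaps_reverse(self):
        d = self._simulate()
        truth = SizeFactorSet(d.true_bias)
        none = SizeFactorSet(np.ones(80))
        bad = offset_covariate_assessment(d.counts, none, truth, fdr=0.05)
        good = offset_covariate_assessment(d.counts, truth, none, fdr=0.05)
        assert bad["n_rejected"] > 20
        assert good["n_rejected"] < bad["n_rejected"]

    def test_null_calibration_across_seeds(self):
        """With correct offsets and an irrelevant covariate, rejections stay rare."""
        fractions = []
        rng = np.random.default_rng(99)
        for seed in range(20):
            cfg = SimulationConfig(n_genes=60, subpop_sizes=(60,), up_fraction=(0.5,),
                                   up_fold=(5.0,), seed=seed)
            d = simulate_counts(cfg)
            noise = SizeFactorSet(2.0 ** rng.normal(0, 0.5, 60))
            out = offset_covariate_assessment(
                d.counts, SizeFactorSet(d.true_bias), noise, fdr=0.05
            )
            if out["n_tested"]:
                fractions.append(out["n_rejected"] / out["n_tested"])
        assert np.mean(fractions) < 0.05

    def test_rejects_invalid_inputs(self, small_counts):
        zeros = SizeFactorSet(np.array([1.0] * 11 + [0.0]))
        ones = SizeFactorSet(np.ones(12))
        with pytest.raises(ValueError):
            offset_covariate_assessment(small_counts, zeros, ones)
        with pytest.raises(ValueError):
            offset_covariate_assessment(small_counts, ones, ones, fdr=1.5)


class TestDistanceToMedian:
    def test_constant_cv2_at_equal_abundance_gives_zero(self):
        r = np.random.default_rng(0)
        base = r.normal(10.0, 1.0, size=40)
        expr = np.tile(base, (30, 1))  # every gene same profile: same mean, same CV^2
        stat = distance_to_median(expr, window=7)
        assert np.allclose(stat, 0.0, atol=1e-12)

    def test_spiked_gene_ranks_first(self):
        r = np.random.default_rng(1)
        expr = 10.0 + r.normal(0, 0.5, size=(50, 40))
        expr[13] = 10.0 + r.normal(0, 6.0, size=40)  # one highly variable gene
        stat = distance_to_median(expr, window=11)
        assert np.nanargmax(stat) == 13

    def test_matches_sliding_median_oracle(self):
        r = np.random.default_rng(2)
        expr = r.gamma(3.0, 2.0, size=(200, 25))
        window = 50
        stat = distance_to_median(expr, window=window)
        mean = expr.mean(axis=1)
        cv2 = expr.var(axis=1, ddof=1) / mean**2
        order = np.argsort(mean, kind="stable")
        running = running_median_oracle(cv2[order], window)
        want = np.empty(200)
        want[order] = cv2[order] - running
        assert np.allclose(stat, want, rtol=1e-12)

    def test_zero_mean_genes_excluded(self):
        expr = np.vstack([np.zeros((1, 10)), np.ones((5, 10)) * np.arange(1, 11)])
        stat = distance_to_median(expr, window=3)
        assert np.isnan(stat[0]) and np.isfinite(stat[1:]).all()


class TestFilterLowAbundance:
    def test_boundary_inclusive(self):
        values = np.zeros((3, 10), dtype=int)
        values[0, :2] = 1          # mean 0.2 -> kept
        values[1, 0] = 1           # mean 0.1 -> removed
        values[2] = 3              # mean 3   -> kept
        out = filter_low_abundance(CountMatrix(values), min_mean=0.2)
        assert out.gene_ids == ["gene_0", "gene_2"]

    def test_all_zero_genes_always_removed(self, small_counts):
        values = small_counts.values.copy()
        values[4] = 0
        out = filter_low_abundance(CountMatrix(values), min_mean=0.0)
        assert "gene_4" not in out.gene_ids

    def test_hand_counted_survivors(self):
        r = np.random.default_rng(6)
        values = r.poisson(0.3, size=(10, 20))
        expected = int((values.mean(axis=1) >= 0.2).sum())
        out = filter_low_abundance(CountMatrix(values), min_mean=0.2)
        assert out.n_genes == expected

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            filter_low_abundance(CountMatrix(np.zeros((2, 4), dtype=int)), min_mean=0.5)
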