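# pooldeconv

Size factor estimation for single-cell RNA-seq count matrices with many
zero counts, by **pooling cells and deconvolving pooled size factors**
— together with the standard comparator normalizers (library size,
median-of-ratios, TMM), a negative-binomial count simulator with
dropout, rank-correlation pre-clustering, and accuracy assessment
tools.

## The problem

scRNA-seq counts carry a cell-specific technical bias θ_j (capture
efficiency, sequencing depth): for a non-DE gene *i* in cell *j*,
E(Y_ij) = θ_j λ_i0. Downstream comparisons require dividing each cell
by an estimate of θ_j (its *size factor*). Ratio-based bulk normalizers
(median-of-ratios, TMM) break down when 40–60 % of counts are zero:
their zero-removal workarounds systematically overestimate the factors
of shallow cells and underestimate those of deep cells, while plain
library-size scaling is distorted by composition bias whenever genes
are differentially expressed.

## The method

Counts are adjusted by t_j (the library size), cells are arranged on a
ring ordered by library size, and sliding windows of sizes
w ∈ {20, 40, 60, 80, 100} define pools S_k of similar depth. The pooled
profile V_ik = Σ_{j∈S_k} Y_ij / t_j, normalized against the averaged
reference pseudo-cell U_i by a median of gene-wise ratios, estimates

  E(R_ik) = Σ_{j∈S_k} θ_j t_j⁻¹ / C,

one linear equation per pool in the per-cell unknowns θ_j t_j⁻¹.
Summation leaves few zeroes, so the pool medians are accurate; solving
the resulting overdetermined system by weighted least squares
(low-weight per-cell anchor equations guarantee full column rank; a
non-negative re-solve guards against negative factors) "deconvolves"
the pool factors into per-cell factors. Multiplying by t_j and
centering yields the size factors. With heterogeneous populations,
cells are pre-clustered on Spearman-correlation distances; each
cluster is deconvolved against its own pseudo-cell and cluster factors
are rescaled through pairwise median ratios τ_C of pseudo-cells
against a baseline, so only a *pairwise* non-DE majority is needed.

## Worked example

```python
import numpy as np
from pooldeconv import (SimulationConfig, simulate_counts,
                        compute_sum_factors, median_ratio_factors)

data = simulate_counts(SimulationConfig(n_genes=2000, subpop_sizes=(80, 80, 80), seed=4))
truth = data.true_bias

for name, est in (
    ("median-ratio", median_ratio_factors(data.counts).factor),
    ("deconvolution", compute_sum_factors(data.counts).factors.factor),
):
    est = est * truth.mean() / est.mean()
    slope = np.polyfit(np.log(truth), np.log(est), 1)[0]
    print(name, round(slope, 3), round(float(np.median(np.abs(np.log(est / truth)))), 4))
```

prints

```
median-ratio 0.471 0.1137
deconvolution 1.003 0.0282
```

The slope of log-estimate on log-truth is ~0.47 for median-of-ratios —
the compression caused by removing stochastic zeroes — against ~1.0
for deconvolution, whose median absolute log-error is four times
smaller. The `examples/` directory walks through each capability
(simulation, baselines, deconvolution, clustering rescue, benchmarking,
offset/covariate comparison); `pooldeconv --help` exposes the same
operations as a command line (`simulate`, `normalize`, `cluster`,
`benchmark`).

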