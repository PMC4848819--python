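"""Run the three baseline normalizers and compare them to the truth.

On data with many zeros, the ratio-based methods (median-of-ratios and
TMM) compress their estimates: the regression slope of log(estimate)
on log(truth) falls well below 1.  Library size normalization is
unbiased here because there is no differential expression.
"""

import numpy as np

from pooldeconv import (
    SimulationConfig,
    library_size_factors,
    median_ratio_factors,
    simulate_counts,
    tmm_factors,
)

data = simulate_counts(SimulationConfig(n_genes=2000, subpop_sizes=(80, 80, 80), seed=4))
truth = data.true_bias

for name, fn in (
    ("library size", library_size_factors),
    ("median-ratio", median_ratio_factors),
    ("TMM", tmm_factors),
):
    est = fn(data.counts).factor
    est = est * truth.mean() / est.mean()  # match grand means
    slope = np.polyfit(np.log(truth), np.log(est), 1)[0]
    med_err = np.median(np.abs(np.log(est / truth)))
    print(f"{name:>13}: slope {slope:.3f}   median |log error| {med_err:.4f}")

# A slope of ~0.45 for median-ratio/TMM means large factors are
# underestimated and small ones overestimated, the hallmark of removing
# stochastic zeros before taking ratios.
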