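# Methods

## Model and procedure

For a non-DE gene *i* in cell *j*, the count is modeled as
E(Y_ij) = θ_j λ_i0, where θ_j is the cell-specific bias to be
estimated (the size factor, up to one global constant) and λ_i0 the
expected transcript count. The estimator works on adjusted values
Z_ij = Y_ij / t_j with t_j fixed at the observed library size: this
equalizes each cell's influence on pooled sums and medians and keeps
small libraries from being swamped by estimation errors of large ones.
The procedure is valid for any fixed positive t_j.

For a pool of cells S_k, the summed profile V_ik = Σ_{S_k} Z_ij is
normalized against the averaged reference pseudo-cell
U_i = N⁻¹ Σ_all Z_ij. For non-DE genes,
E(R_ik) = E(V_ik)/E(U_i) = Σ_{S_k} θ_j t_j⁻¹ / C with a single global
constant C (set to 1; it cancels in the final centering). The pool
factor is estimated as the **median** of the observed ratios
r_ik = v_ik/u_ik over genes with u_i > 0: a robust average that
tolerates a minority of DE genes with extreme ratios. Each pool gives
one linear equation in the unknowns x_j = θ_j t_j⁻¹; many pools give
an overdetermined system; the weighted least-squares solution, times
t_j, gives the size factors ("deconvolution" of pool factors into cell
factors). Summation is the point: pooled profiles contain few zeroes,
so their ratio medians avoid the compression bias that single-cell
ratio methods suffer.

### Pool selection

Cells are ranked by decreasing library size and arranged on a ring:
rank 1 first, even ranks continuing with decreasing size to the
smallest cell at the antipode, odd ranks returning with increasing
size. Sliding a window of size w cell-by-cell around the ring (with
wrap-around) yields exactly n pools per window size, each cell
belonging to exactly w of them; the defaults w = 20, 40, 60, 80, 100
put every cell in 300 pool equations. Windows therefore hold cells of
similar library size, which stops small x_j from being grouped with
(and overwhelmed by the estimation error of) much larger ones. Any
rotation or reflection of the ring yields the same pool multiset, so
the start position is purely cosmetic. A `pool_strategy="random"`
variant slides the same windows over a randomly permuted arrangement —
same number and sizes of pools, every cell still covered — isolating
the effect of the ordering; in reduced-scale simulations the ring
lowers the RMSE of log-factors by roughly a factor 2 (0.043 vs 0.085,
20/20 seeds).

### Solvability, non-negativity, standard errors

Window-sum (circulant) coefficient blocks are rank deficient — with an
even window size the alternating ring vector is annihilated — so one
anchor equation per cell (x_j equals the cell's own single-cell
median-ratio estimate, zero ratios removed, defaulting to 1 when
undefined) is appended with weight 10⁻⁶ against the pool rows' weight
1. The anchors make the columns linearly independent while
contributing negligibly to the solution.

The weighted system is solved by QR-based least squares on the
sqrt-weight-scaled rows (`scipy.linalg.lstsq`). Normal equations were
rejected: they square the condition number of the pool blocks and left
~10⁻⁷ relative error on exactly consistent systems, versus ~10⁻¹³ for
QR. If any estimate is negative — possible for cells whose true
x_j is near zero — the system is re-solved under non-negativity
(`scipy.optimize.nnls`); cells pinned at exactly zero are counted and
flagged, not dropped, and should be discarded by the user as likely
low-quality libraries. The unconstrained path is the fast default; the
constrained solve runs only on detection of a negative estimate
(relative tolerance 10⁻¹⁰).

Standard errors use a sandwich covariance with separate residual
variances for pool rows and anchor rows. The textbook WLS covariance
σ²(AᵀWA)⁻¹ interprets the anchor weight 10⁻⁶ as an inverse variance,
which inflates the variance of the near-null alternating mode by ~10⁶
and yields absurd SEs (tens of times the factor itself); estimating
each row class's variance from its own residuals gives SEs on the
order of 5–50 % of a mean-one factor in the default simulations.
Clamped cells get no SE: the distribution of an active-constraint
estimate is not normal and we do not pretend otherwise.

### Clustering and rescaling

The pool-median is only trustworthy when fewer than half the genes are
DE between a pool and the reference in either direction. With
heterogeneous data, cells are first clustered on the distance
√((1 − ρ)/2), ρ the Spearman correlation of count profiles — rank
based, hence invariant to the very cell-specific scaling being
estimated, avoiding circularity. Ward-linkage hierarchical clustering
is cut starting from ⌊n/min_size⌋ clusters, greedily merging any
undersized cluster into the cluster with the smallest mean
inter-cluster distance (a deterministic, documented cut rule; the
default min_size = 200 accommodates the largest default window).
Deconvolution runs within each cluster against a cluster-specific
pseudo-cell, giving factors f_j on a per-cluster scale; cluster
pseudo-cells are then normalized pairwise against a baseline
pseudo-cell by the median ratio τ_C over genes positive in both
(baseline τ = 1), and the final factor is f_j·τ_C, recentered to grand
mean 1. The baseline is the cluster whose pseudo-cell has the median
total — a central choice that keeps all τ ratios moderate. Per-cluster
factors enter the rescaling *uncentered*: centering them first would
sever the scale link between f_j and the cluster pseudo-cell that τ_C
relies on. Pairwise rescaling only needs a non-DE majority between
cluster pairs: five subpopulations with disjoint 20 %-of-genes
signatures leave 100 % of genes DE globally but only 40 % per pair,
and the clustered estimator still recovers the truth (Spearman > 0.98
in the packaged example).

## Baseline normalizers

*Library size*: factor ∝ column total; robust to zeroes, broken by
composition bias under DE. *Median-of-ratios*: reference per gene =
geometric mean of the **non-zero** counts (all-zero genes dropped);
factor = median over genes of count/reference with zero ratios removed
(even-length medians use the arithmetic midpoint of the two central
ratios — the one observable difference from DESeq2, which takes
medians on the log scale); an optional pseudo-count (plain or scaled
to relative library size) is exposed, and a large one demonstrably
squeezes all factors to 1. *TMM*: reference cell = the one whose 75th
percentile of library-size-normalized counts is nearest the mean of
those percentiles; M and A values over genes non-zero in both
libraries; double trim (30 % on M, 5 % on A, rank-based with
floor(n·trim)+1 cut points); precision weights are inverse asymptotic
binomial variances (N−y)/(Ny) summed over the two libraries;
normalization factors rescaled to multiply to 1; size factor =
normalization factor × library size. Both re-implementations are
cross-checked in the test suite against edgeR::calcNormFactors and
DESeq2::estimateSizeFactorsForMatrix on a fixture screened to be free
of rank ties (a tie at a trim boundary can resolve differently across
languages in the last floating-point digit).

All returned factor sets are centered so the positive factors average
to 1; comparisons against truth first rescale estimates to the truth's
grand mean, making every reported error invariant to global scaling.

## Simulator

Counts are drawn per (gene, cell) from a negative binomial with mean
θ_j·ϕ_is·λ_i0 and quadratic dispersion φ = 0.1
(variance μ + φμ²), implemented as a gamma–Poisson mixture;
φ = 0 degenerates to Poisson. Defaults: 10,000 genes; three
subpopulations of 250 cells; log2 θ_j ~ N(0, 0.25) *variance* (sd 0.5
— the spread interpretation is exposed as `bias_log2_sd` so the
alternative reading is one argument away); λ_i0 ~ Gamma(2, 2). Each
subpopulation receives G mutually exclusive DE genes, ⌈p_s·G⌉
upregulated by fold ϕ_s and the rest silenced (fold 0 —
semi-systematic zeroes); scenario presets cover G = 0/1000/3000 with
p = (0.2, 0.5, 0.8), ϕ = 5, and a varying-magnitude variant
(G = 3000, p = 0.5, ϕ = 2/5/10). Under the defaults ~46 % of counts
per cell are zero, inside the 40–50 % regime the parameters target. A
high-coverage preset multiplies the gamma scale of λ_i0 by 10 (zero
fraction ~4 %). One seeded generator with a fixed draw order (biases,
baseline means, DE assignment, counts gene-major) makes every dataset
bit-reproducible.

The simulator emulates dropout as pure NB sampling variance with a
constant dispersion and independent genes. It does not model
amplification noise, UMI collisions, batch effects, gene–gene
correlation, or empirical mean–dispersion trends; passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not performance guarantees on any particular real
dataset.

## Assessment tools

`benchmark` simulates, runs each method, matches grand means, and
reports per-cell log-ratio errors with per-subpopulation breakdowns;
method failures are recorded per seed, not fatal.
`offset_covariate_assessment` compares two factor sets without ground
truth: per gene, an NB log-link GLM on a homogeneous cell group with
one set's log-factors as offset and the other's centered log-factors
as covariate; a Wald test of the covariate coefficient, BH-corrected
at FDR 5 %, counts genes whose means the offsets fail to explain.
Dispersion is a per-gene method-of-moments estimate (floored at 10⁻⁸)
from a Poisson fit's means — a simple documented estimator; exact
parity with any particular empirical-Bayes pipeline is out of scope.
Non-convergent genes are skipped and counted.
`distance_to_median` ranks highly variable genes by CV² minus a
running median of CV² over the 50 genes of most similar mean abundance
(fixed-width window, clamped at the edges). `filter_low_abundance`
removes genes with mean count below 0.2 (boundary inclusive; all-zero
genes always removed as systematic zeroes).

## Problem sizes used in tests

The test suite and examples run reduced-scale versions of the
simulation scenarios — typically 1000–2000 genes and 60–80 cells per
subpopulation, with DE gene counts scaled proportionally (e.g. 600 of
2000 genes per subpopulation for the strong-DE scenario, keeping the
90 %-DE structure) and 20 seeds for method comparisons. Comparison
thresholds in the acceptance tests (slopes < 0.8 for the ratio
methods, error bounds for library size, strict ordering for
deconvolution) were fixed once from a pilot run of the same protocol.
The simulator-calibration checks (zero-fraction band, 9000-DE-gene
bookkeeping) run at the full default scale.

## Known limitations

- Pool medians treat genes with u_i > 0 but v_ik = 0 as genuine ratios
  of 0 (a zero surviving summation over a whole pool is signal); other
  implementations may drop them instead.
- The SE estimator under active non-negativity constraints is
  undefined here by design (clamped cells get NaN).
- Worst-case solver cost grows as n³ in the number of cells within one
  cluster; pre-clustering bounds the blocks but very large homogeneous
  datasets will be slow.
- TMM is only approximately scale-equivariant in a single column (its
  precision weights mix terms from both libraries), and exact numeric
  parity with external implementations is not guaranteed on inputs
  with tied M/A values.
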