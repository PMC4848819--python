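"""Accuracy assessment of size factor estimates.

Two assessment routes are provided.  On simulated data, estimated
factors are compared directly to the known cell biases after matching
grand means (:func:`benchmark`).  When truth is unknown, two competing
factor sets can be compared via per-gene negative-binomial GLMs on a
homogeneous group of cells: one set enters as the model offset, the
other as a covariate, and a covariate that still explains variation in
the mean counts indicates that the offsets missed part of the
cell-specific bias (:func:`offset_covariate_assessment`).

Also included: the distance-to-median statistic for highly variable
gene detection, and the low-abundance gene filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from ._matrix import CountMatrix, SizeFactorSet
from .simulate import SimulationConfig, SimulatedDataset, simulate_counts

__all__ = [
    "AccuracyReport",
    "benchmark",
    "summarize_reports",
    "offset_covariate_assessment",
    "distance_to_median",
    "filter_low_abundance",
]

MethodFn = Callable[[CountMatrix], SizeFactorSet]


@dataclass
class AccuracyReport:
    """Per-cell estimation errors of one method on one simulated dataset.

    Errors are ``log(estimate_j / theta_j)`` after rescaling the
    estimates so their grand mean matches the grand mean of the true
    biases; they are therefore invariant to any global rescaling of
    either factor set.  ``slope`` is the least-squares slope of
    ``log(estimate)`` on ``log(theta)`` — below 1 indicates the
    compression pattern where large factors are underestimated and
    small ones overestimated.
    """

    method: str
    seed: int
    log_errors: np.ndarray
    subpop_label: np.ndarray
    failed: bool = False
    message: str = ""
    slope: float = np.nan
    pearson_log: float = np.nan
    n_zero_estimates: int = 0

    @property
    def median_abs_error(self) -> float:
        return float(np.median(np.abs(self.log_errors)))

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.log_errors**2)))

    def per_subpop_mean_error(self) -> dict:
        return {
            int(s): float(self.log_errors[self.subpop_label == s].mean())
            for s in np.unique(self.subpop_label)
        }


def _assess(
    method: str, seed: int, estimate: SizeFactorSet, truth: np.ndarray, label: np.ndarray
) -> AccuracyReport:
    est = estimate.factor.astype(float)
    ok = est > 0
    n_zero = int((~ok).sum())
    est_matched = est * truth.mean() / est.mean()  # grand-mean matching
    log_err = np.full(truth.size, np.nan)
    log_err[ok] = np.log(est_matched[ok] / truth[ok])
    lt = np.log(truth[ok])
    le = np.log(est_matched[ok])
    slope = float(np.polyfit(lt, le, 1)[0]) if ok.sum() > 1 else np.nan
    r = float(np.corrcoef(lt, le)[0, 1]) if ok.sum() > 1 else np.nan
    return AccuracyReport(
        method=method,
        seed=seed,
        log_errors=log_err[ok],
        subpop_label=label[ok],
        slope=slope,
        pearson_log=r,
        n_zero_estimates=n_zero,
    )


def benchmark(
    config: SimulationConfig,
    methods: Mapping[str, MethodFn],
    seeds: Sequence[int],
) -> list[AccuracyReport]:
    """Simulate, normalize with each method, and score against truth.

    One :class:`AccuracyReport` per (method, seed).  A method that
    raises on some seed yields a report flagged ``failed`` instead of
    aborting the whole comparison.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    reports = []
    for seed in seeds:
        data: SimulatedDataset = simulate_counts(replace(config, seed=int(seed)))
        for name, fn in methods.items():
            try:
                est = fn(data.counts)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                reports.append(
                    AccuracyReport(
                        method=name,
                        seed=int(seed),
                        log_errors=np.array([]),
                        subpop_label=np.array([]),
                        failed=True,
                        message=str(exc),
                    )
                )
                continue
            reports.append(_assess(name, int(seed), est, data.true_bias, data.subpop_label))
    return reports


def summarize_reports(reports: list[AccuracyReport]) -> pd.DataFrame:
    """Average the per-report summaries over seeds, one row per method."""
    rows = []
    for rep in reports:
        if rep.failed:
            continue
        row = {
            "method": rep.method,
            "seed": rep.seed,
            "median_abs_error": rep.median_abs_error,
            "rmse": rep.rmse,
            "slope": rep.slope,
            "pearson_log": rep.pearson_log,
            "n_zero_estimates": rep.n_zero_estimates,
        }
        for s, e in rep.per_subpop_mean_error().items():
            row[f"mean_error_subpop{s}"] = e
        rows.append(row)
    if not rows:
        raise ValueError("no successful reports to summarize")
    df = pd.DataFrame(rows)
    return df.drop(columns="seed").groupby("method", sort=False).mean().reset_index()


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion given fitted means."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    if den <= 0:
        return floor
    return float(max(num / den, floor))


def offset_covariate_assessment(
    counts: CountMatrix,
    offsets: SizeFactorSet,
    covariate: SizeFactorSet,
    fdr: float = 0.05,
) -> dict:
    """Count genes whose means the offsets fail to explain.

    For each gene a negative-binomial log-link GLM is fitted with
    ``log(offset factors)`` as offset and the centered log of the
    competing factors as a single covariate.  If the offsets capture
    the cell-specific biases fully, the covariate coefficient is zero;
    rejections of that null (Wald test, Benjamini-Hochberg at ``fdr``)
    therefore count the genes with residual unmodeled bias.  Intended
    for a single homogeneous group of cells (no DE within the group).

    Returns a dict with ``n_rejected``, ``n_tested``, ``n_failed`` and
    the per-gene ``pvalues``.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if np.any(offsets.factor <= 0) or np.any(covariate.factor <= 0):
        raise ValueError("offset and covariate factors must be strictly positive")
    off = np.log(offsets.factor)
    cov = np.log(covariate.factor)
    cov = cov - cov.mean()
    x = np.column_stack([np.ones_like(cov), cov])

    pvals, failed = [], 0
    for i in range(counts.n_genes):
        y = counts.values[i].astype(float)
        if y.sum() == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, x, family=sm.families.Poisson(), offset=off).fit()
                alpha = _moment_dispersion(y, pois.fittedvalues)
                nb = sm.GLM(
                    y, x, family=sm.families.NegativeBinomial(alpha=alpha), offset=off
                ).fit()
            p = float(nb.pvalues[1])
            if not np.isfinite(p):
                raise ValueError("non-finite p-value")
        except Exception:  # noqa: BLE001 - non-convergent genes are skipped
            failed += 1
            continue
        pvals.append(p)
    pvals = np.asarray(pvals)
    if pvals.size == 0:
        return {"n_rejected": 0, "n_tested": 0, "n_failed": failed, "pvalues": pvals}
    rej = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    return {
        "n_rejected": int(rej.sum()),
        "n_tested": int(pvals.size),
        "n_failed": failed,
        "pvalues": pvals,
    }


def distance_to_median(
    normalized_expression: np.ndarray, window: int = 50
) -> np.ndarray:
    """Distance-to-median variability statistic per gene.

    The squared coefficient of variation (CV^2) of each gene's
    normalized expression across cells, minus a running median of CV^2
    over the ``window`` genes of most similar mean abundance.  Large
    positive values mark genes more variable than others of comparable
    abundance.  Genes with zero mean get NaN.
    """
    expr = np.asarray(normalized_expression, dtype=float)
    if expr.ndim != 2:
        raise ValueError("expected a genes x cells matrix")
    if window < 1 or window > expr.shape[0]:
        raise ValueError("window must lie in [1, n_genes]")
    mean = expr.mean(axis=1)
    out = np.full(expr.shape[0], np.nan)
    ok = mean > 0
    cv2 = np.full(expr.shape[0], np.nan)
    cv2[ok] = expr[ok].var(axis=1, ddof=1) / mean[ok] ** 2

    idx = np.flatnonzero(ok)
    order = idx[np.argsort(mean[idx], kind="stable")]
    sorted_cv2 = cv2[order]
    n = order.size
    half = window // 2
    running = np.empty(n)
    for pos in range(n):
        lo = max(0, min(pos - half, n - window))
        running[pos] = np.median(sorted_cv2[lo : lo + window])
    out[order] = sorted_cv2 - running
    return out


def filter_low_abundance(counts: CountMatrix, min_mean: float = 0.2) -> CountMatrix:
    """Drop genes with an average count below ``min_mean`` across cells.

    Such genes are dominated by systematic zeroes (with occasional
    counts from residual transcription or mapping error) and carry
    mostly noise into ratio-based normalization.  The boundary is
    inclusive: a gene with mean exactly ``min_mean`` is kept.  Gene
    order is preserved.
    """
    # genes silent in every cell are systematic zeroes: uninformative, always out
    keep = (counts.values.mean(axis=1) >= min_mean) & counts.values.any(axis=1)
    if not keep.any():
        raise ValueError("no genes pass the abundance filter")
    return counts.subset_genes(keep)
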