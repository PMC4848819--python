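"""Comparator normalizers: library size, median-of-ratios, and TMM.

These are the three scaling-normalization strategies routinely applied
to bulk RNA-seq counts, re-implemented here with the zero-handling
workarounds needed to run them on sparse single-cell counts: the
median-of-ratios reference uses geometric means over *non-zero* counts
only, zero ratios are dropped before taking the per-cell median, and
undefined M values (a zero in either library) are removed before TMM
trimming.  These workarounds keep the methods computable but introduce
the compression bias that the pooling/deconvolution approach in
:mod:`pooldeconv.deconvolution` is designed to avoid.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from ._matrix import CountMatrix, SizeFactorSet

__all__ = ["library_size_factors", "median_ratio_factors", "tmm_factors"]


def _check_normalizable(counts: CountMatrix) -> None:
    if counts.n_cells < 2:
        raise ValueError("normalization requires at least 2 cells")
    if counts.n_genes < 1:
        raise ValueError("normalization requires at least 1 gene")


def _require_positive_totals(counts: CountMatrix) -> np.ndarray:
    totals = counts.library_sizes()
    if np.any(totals == 0):
        j = int(np.argmin(totals))
        raise ValueError(f"cell {counts.cell_ids[j]!r} has a total count of zero")
    return totals


def library_size_factors(counts: CountMatrix) -> SizeFactorSet:
    """Size factors proportional to the total count of each cell.

    Robust to zeroes (they simply do not contribute to the sum) but not
    to differential expression: composition shifts move the library
    size and are absorbed into the factor.
    """
    _check_normalizable(counts)
    totals = _require_positive_totals(counts).astype(float)
    return SizeFactorSet(totals, counts.cell_ids).centered("mean_one")


def median_ratio_factors(
    counts: CountMatrix,
    pseudo_count: float = 0.0,
    scale_pseudo_by_libsize: bool = False,
) -> SizeFactorSet:
    """Median-of-ratios (DESeq-style) size factors with zero workarounds.

    A reference pseudo-library is built per gene as the geometric mean
    of that gene's **non-zero** counts across cells (all-zero genes are
    dropped).  Each cell's factor is the median, over genes, of the
    ratio of its count to the reference; when no pseudo-count is added,
    zero ratios are removed before the median so the factor is not
    dragged to zero by dropout.

    Parameters
    ----------
    pseudo_count
        Constant added to every count before forming ratios.  A large
        value squeezes all factors towards 1.
    scale_pseudo_by_libsize
        If true, the pseudo-count added to cell ``j`` is scaled by that
        cell's library size relative to the mean library size.
    """
    _check_normalizable(counts)
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    y = counts.values.astype(float)
    nonzero = y > 0
    expressed = nonzero.any(axis=1)
    if not expressed.any():
        raise ValueError("all counts are zero; cannot normalize")
    y = y[expressed]
    nonzero = nonzero[expressed]

    with np.errstate(divide="ignore"):
        logs = np.where(nonzero, np.log(y, where=nonzero, out=np.zeros_like(y)), 0.0)
    reference = np.exp(logs.sum(axis=1) / nonzero.sum(axis=1))

    if pseudo_count > 0 and scale_pseudo_by_libsize:
        lib = counts.library_sizes().astype(float)
        pc = pseudo_count * lib / lib.mean()
    else:
        pc = np.full(counts.n_cells, float(pseudo_count))

    factors = np.empty(counts.n_cells)
    for j in range(counts.n_cells):
        ratios = (y[:, j] + pc[j]) / reference
        if pseudo_count == 0:
            ratios = ratios[ratios > 0]
        if ratios.size == 0:
            warnings.warn(
                f"cell {counts.cell_ids[j]!r} has no usable ratios; size factor set to 0",
                stacklevel=2,
            )
            factors[j] = 0.0
        else:
            factors[j] = np.median(ratios)
    return SizeFactorSet(factors, counts.cell_ids).centered("mean_one")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float | None:
    """TMM normalization factor of one library against the reference.

    Returns ``None`` when no genes survive trimming.  Follows the
    canonical TMM recipe: double trim on M (log2 ratio of library-size-
    normalized proportions) and A (average log2 abundance), then a
    precision-weighted mean of the surviving M values using the inverse
    asymptotic binomial variance
    ``(n_obs - y_obs)/(n_obs * y_obs) + (n_ref - y_ref)/(n_ref * y_ref)``
    as weight.
    """
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return None
    yo, yr = obs[both].astype(float), ref[both].astype(float)
    po, pr = yo / n_obs, yr / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = 1.0 / ((n_obs - yo) / (n_obs * yo) + (n_ref - yr) / (n_ref * yr))

    if np.max(np.abs(m)) < 1e-6:  # effectively identical libraries
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return None
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> SizeFactorSet:
    """Trimmed-mean-of-M-values size factors (effective library sizes).

    The reference cell is the one whose 75th percentile of library-size-
    normalized counts is closest to the mean of those percentiles.  Each
    cell's normalization factor is the double-trimmed, precision-weighted
    mean of its M values against the reference; undefined M values
    (zero count in either library) are removed first.  Normalization
    factors are rescaled to multiply to 1, and the size factor is the
    effective library size: normalization factor x library size.
    """
    _check_normalizable(counts)
    if not (0 <= trim_m < 0.5) or not (0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    totals = _require_positive_totals(counts).astype(float)
    y = counts.values

    q75 = np.quantile(y, 0.75, axis=0) / totals
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    nf = np.empty(counts.n_cells)
    for j in range(counts.n_cells):
        if j == ref_idx:
            nf[j] = 1.0
            continue
        f = _tmm_pair(y[:, j], y[:, ref_idx], totals[j], totals[ref_idx], trim_m, trim_a)
        if f is None:
            warnings.warn(
                f"cell {counts.cell_ids[j]!r}: no genes survive TMM trimming; "
                "falling back to library size (normalization factor 1)",
                stacklevel=2,
            )
            f = 1.0
        nf[j] = f
    nf /= np.exp(np.mean(np.log(nf)))  # factors multiply to 1
    return SizeFactorSet(nf * totals, counts.cell_ids).centered("mean_one")
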