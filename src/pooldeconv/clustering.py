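"""Pre-clustering of cells and rescaling of per-cluster size factors.

Deconvolving within clusters of transcriptionally similar cells weakens
the non-DE-majority assumption: within a cluster few genes are DE, and
across clusters only a *pairwise* non-DE majority (each cluster's
pseudo-cell against one baseline pseudo-cell) is needed, rather than a
majority of genes constant across the whole dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from ._matrix import CountMatrix, SizeFactorSet

__all__ = ["ClusterAssignment", "ClusterRescaling", "quick_cluster", "rescale_clusters"]


@dataclass
class ClusterAssignment:
    """A partition of cells into clusters of at least ``min_size`` cells."""

    label: np.ndarray
    min_size: int

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label)
        _, counts = np.unique(self.label, return_counts=True)
        if counts.min() < self.min_size:
            raise ValueError("every cluster must contain at least min_size cells")

    @property
    def n_clusters(self) -> int:
        return np.unique(self.label).size

    def sizes(self) -> dict:
        uniq, counts = np.unique(self.label, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


@dataclass
class ClusterRescaling:
    """Per-cluster rescaling constants against a baseline cluster."""

    tau: dict
    baseline_cluster: object

    def __post_init__(self) -> None:
        if not np.isclose(self.tau[self.baseline_cluster], 1.0):
            raise ValueError("the baseline cluster must have tau = 1")
        if any(t <= 0 for t in self.tau.values()):
            raise ValueError("rescaling constants must be positive")


def _spearman_distance(values: np.ndarray) -> np.ndarray:
    """Pairwise cell distance sqrt((1 - rho)/2), rho = Spearman correlation.

    Rank correlations depend only on the ordering of counts within each
    cell, so the distances are invariant to cell-specific scaling — the
    clustering cannot be circular with respect to the normalization it
    precedes.  Ties receive average ranks.
    """
    ranks = np.apply_along_axis(rankdata, 0, values.astype(float))
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    return np.sqrt((1.0 - rho) / 2.0)


def quick_cluster(counts: CountMatrix, min_size: int = 200) -> ClusterAssignment:
    """Hierarchically cluster cells on rank-correlation distances.

    Ward-linkage hierarchical clustering on the Spearman distance
    matrix; the tree is cut to the finest partition compatible with the
    size constraint by starting from ``n // min_size`` clusters and
    greedily merging any undersized cluster into the cluster nearest to
    it (smallest mean inter-cluster distance).  Deterministic.

    The default ``min_size`` of 200 comfortably accommodates the
    default deconvolution window sizes (largest 100).
    """
    if min_size <= 0:
        raise ValueError("min_size must be positive")
    n = counts.n_cells
    if n < min_size:
        warnings.warn(
            f"only {n} cells for min_size={min_size}; returning a single cluster",
            stacklevel=2,
        )
        return ClusterAssignment(np.zeros(n, dtype=int), min_size=n)

    dist = _spearman_distance(counts.values)
    z = linkage(squareform(dist, checks=False), method="ward")
    k_max = n // min_size
    labels = fcluster(z, t=k_max, criterion="maxclust") - 1

    # greedily merge undersized clusters into their nearest neighbour
    while True:
        uniq, sizes = np.unique(labels, return_counts=True)
        if sizes.min() >= min_size or uniq.size == 1:
            break
        small = uniq[np.argmin(sizes)]
        members = labels == small
        best, best_d = None, np.inf
        for other in uniq:
            if other == small:
                continue
            d = dist[np.ix_(members, labels == other)].mean()
            if d < best_d:
                best, best_d = other, d
        labels[members] = best

    # relabel to consecutive integers in order of first appearance
    remap = {lab: i for i, lab in enumerate(dict.fromkeys(labels.tolist()))}
    labels = np.array([remap[lab] for lab in labels])
    return ClusterAssignment(labels, min_size=min_size)


def rescale_clusters(
    per_cluster_factors: list[SizeFactorSet],
    pseudo_cells: list[np.ndarray],
    return_rescaling: bool = False,
):
    """Put per-cluster size factors on a common scale.

    Each cluster's pseudo-cell (averaged adjusted expression profile) is
    normalized against a single baseline pseudo-cell by a median of
    gene-wise ratios, giving a constant ``tau_C`` per cluster (the
    baseline's ``tau`` is exactly 1).  Cell ``j`` of cluster ``C`` gets
    the final factor ``f_j * tau_C``; the combined set is recentered to
    mean 1 across all cells.

    The baseline is the cluster whose pseudo-cell has the median total
    (the middle of the depth range), which keeps the ratios involved in
    every ``tau_C`` moderate.

    Returns a list of rescaled :class:`SizeFactorSet`, one per cluster
    (and the :class:`ClusterRescaling` if requested).
    """
    if len(per_cluster_factors) != len(pseudo_cells):
        raise ValueError("need one pseudo-cell per cluster factor set")
    if not per_cluster_factors:
        raise ValueError("no clusters supplied")
    profiles = [np.asarray(p, dtype=float) for p in pseudo_cells]
    n_genes = profiles[0].size
    if any(p.size != n_genes for p in profiles):
        raise ValueError("pseudo-cells must share the same gene index")

    totals = np.array([p.sum() for p in profiles])
    order = np.argsort(totals, kind="stable")
    baseline = int(order[order.size // 2]) if order.size % 2 else int(order[order.size // 2 - 1])

    base = profiles[baseline]
    tau = {}
    for c, prof in enumerate(profiles):
        if c == baseline:
            tau[c] = 1.0
            continue
        shared = (prof > 0) & (base > 0)
        if not shared.any():
            raise ValueError(
                f"cluster {c} shares no positively expressed genes with the baseline"
            )
        tau[c] = float(np.median(prof[shared] / base[shared]))

    grand = np.concatenate(
        [s.factor * tau[c] for c, s in enumerate(per_cluster_factors)]
    )
    scale = grand[grand > 0].mean()
    rescaled = []
    for c, s in enumerate(per_cluster_factors):
        se = None if s.std_error is None else s.std_error * tau[c] / scale
        # the grand mean over all clusters is 1; each per-cluster subset on
        # its own is not recentered, hence "raw"
        rescaled.append(SizeFactorSet(s.factor * tau[c] / scale, s.cell_ids, se))
    if return_rescaling:
        return rescaled, ClusterRescaling(tau, baseline)
    return rescaled
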