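"""Core in-memory containers: count matrices and per-cell size factors.

The orientation convention throughout this package is **genes as rows,
cells as columns** (``values[i, j]`` is the count of gene ``i`` in cell
``j``).  This matches the usual statistical notation for RNA-seq counts
but is transposed relative to some Python single-cell ecosystems
(e.g. AnnData stores cells as rows), so be careful when converting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "SizeFactorSet"]


def _as_dense_counts(values) -> np.ndarray:
    if sp.issparse(values):
        values = values.toarray()
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"count matrix must be 2-dimensional, got shape {arr.shape}")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        frac = np.mod(arr, 1)
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise ValueError(f"non-integer count at gene row {i}, cell column {j}: {arr[i, j]!r}")
    arr = arr.astype(np.int64, copy=False)
    if arr.size and arr.min() < 0:
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative count at gene row {i}, cell column {j}: {arr[i, j]}")
    return arr


@dataclass
class CountMatrix:
    """A gene-by-cell matrix of non-negative integer counts.

    Parameters
    ----------
    values
        Integer array of shape ``(n_genes, n_cells)``.  Sparse matrices
        and float arrays holding whole numbers are densified/cast.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.  Generated as
        ``gene_0`` ... / ``cell_0`` ... when omitted.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = _as_dense_counts(self.values)
        n_genes, n_cells = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{i}" for i in range(n_genes)]
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{j}" for j in range(n_cells)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} gene rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} cell columns")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for x in ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total count per cell (column sums)."""
        return self.values.sum(axis=0)

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.cell_ids),
        )

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[j] for j in idx],
        )


@dataclass
class SizeFactorSet:
    """One scale factor per cell.

    A size factor is the per-cell scaling constant that removes
    cell-specific technical bias (capture efficiency, sequencing depth);
    dividing a cell's counts by its factor makes expression comparable
    across cells.  A factor of exactly zero marks a cell for which no
    sensible positive estimate exists (these should be removed before
    downstream analysis).

    ``centering`` records the convention used: ``mean_one`` means the
    positive factors average to 1, ``median_one`` that their median is
    1, ``raw`` that no rescaling was applied.
    """

    factor: np.ndarray
    cell_ids: Sequence[str] | None = None
    std_error: np.ndarray | None = None
    centering: str = "raw"

    def __post_init__(self) -> None:
        self.factor = np.asarray(self.factor, dtype=float)
        if self.factor.ndim != 1:
            raise ValueError("size factors must be a 1-d array")
        if np.any(self.factor < 0):
            raise ValueError("size factors must be non-negative")
        if not np.any(self.factor > 0):
            raise ValueError("at least one size factor must be strictly positive")
        if self.std_error is not None:
            self.std_error = np.asarray(self.std_error, dtype=float)
            if self.std_error.shape != self.factor.shape:
                raise ValueError("std_error shape must match factor shape")
        if self.cell_ids is not None and len(self.cell_ids) != self.factor.size:
            raise ValueError("cell_ids length must match number of factors")
        if self.centering not in ("mean_one", "median_one", "raw"):
            raise ValueError(f"unknown centering convention {self.centering!r}")

    @property
    def n_cells(self) -> int:
        return self.factor.size

    def centered(self, mode: str = "mean_one") -> "SizeFactorSet":
        """Return a rescaled copy under the given centering convention.

        Only strictly positive factors enter the centering statistic, so
        zero-flagged cells do not drag the mean/median down.
        """
        pos = self.factor[self.factor > 0]
        if mode == "mean_one":
            scale = pos.mean()
        elif mode == "median_one":
            scale = np.median(pos)
        elif mode == "raw":
            return replace(self)
        else:
            raise ValueError(f"unknown centering convention {mode!r}")
        se = None if self.std_error is None else self.std_error / scale
        return SizeFactorSet(self.factor / scale, self.cell_ids, se, centering=mode)
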