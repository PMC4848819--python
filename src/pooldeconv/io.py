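"""Reading and writing count matrices and size factor tables.

Counts are stored genes-as-rows, cells-as-columns, either as a
MatrixMarket coordinate file with sibling id files
(``<prefix>.mtx`` + ``<prefix>.genes.tsv`` + ``<prefix>.cells.tsv``)
or as a dense TSV/CSV with a header row of cell ids and gene ids in
the first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._matrix import CountMatrix, SizeFactorSet
from .deconvolution import DeconvolutionResult

__all__ = ["read_counts", "write_counts", "read_factors", "write_factors"]


def _sibling_ids(path: Path, kind: str) -> list[str]:
    f = path.parent / (path.name[: -len(path.suffix)] + f".{kind}.tsv")
    if not f.exists():
        raise FileNotFoundError(
            f"expected {kind} id file {f} next to the MatrixMarket file"
        )
    return [line.split("\t")[0] for line in f.read_text().splitlines() if line]


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a gene-by-cell count matrix.

    ``format`` is one of ``mtx``, ``tsv``, ``csv``; inferred from the
    file extension when omitted.  An explicitly stored zero in a
    MatrixMarket file is a zero count, identical to an absent entry.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if sp.issparse(mat):
            mat = mat.toarray()
        genes = _sibling_ids(path, "genes")
        cells = _sibling_ids(path, "cells")
        return CountMatrix(mat, genes, cells)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        # pandas mangles duplicate column names; validate against the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        return CountMatrix(df.to_numpy(), list(df.index.astype(str)), header)
    raise ValueError(f"unknown count matrix format {format!r}")


def write_counts(counts: CountMatrix, prefix: str | Path) -> Path:
    """Write counts as ``<prefix>.mtx`` with sibling gene/cell id files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx = prefix.parent / (prefix.name + ".mtx")
    scipy.io.mmwrite(mtx, sp.coo_matrix(counts.values), field="integer")
    (prefix.parent / (prefix.name + ".genes.tsv")).write_text(
        "".join(f"{g}\n" for g in counts.gene_ids)
    )
    (prefix.parent / (prefix.name + ".cells.tsv")).write_text(
        "".join(f"{c}\n" for c in counts.cell_ids)
    )
    return mtx


def write_factors(result: SizeFactorSet | DeconvolutionResult, path: str | Path) -> Path:
    """Write size factors as a TSV with deterministic formatting.

    Columns: ``cell_id``, ``size_factor`` (10 significant digits),
    ``std_error`` (blank when absent), ``flagged`` (``yes`` for cells
    clamped at zero).
    """
    sfs = result.factors if isinstance(result, DeconvolutionResult) else result
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells = sfs.cell_ids if sfs.cell_ids is not None else [f"cell_{j}" for j in range(sfs.n_cells)]
    lines = ["cell_id\tsize_factor\tstd_error\tflagged"]
    for j, cid in enumerate(cells):
        se = ""
        if sfs.std_error is not None and np.isfinite(sfs.std_error[j]):
            se = f"{sfs.std_error[j]:.10g}"
        flag = "yes" if sfs.factor[j] == 0 else "no"
        lines.append(f"{cid}\t{sfs.factor[j]:.10g}\t{se}\t{flag}")
    path.write_text("".join(f"{ln}\n" for ln in lines))
    return path


def read_factors(path: str | Path) -> SizeFactorSet:
    """Read a size factor TSV written by :func:`write_factors`."""
    df = pd.read_csv(path, sep="\t")
    se = None
    if "std_error" in df and df["std_error"].notna().any():
        se = df["std_error"].to_numpy(dtype=float)
        se = np.where(np.isnan(se), np.nan, se)
    return SizeFactorSet(
        df["size_factor"].to_numpy(dtype=float),
        list(df["cell_id"].astype(str)),
        se,
    )


def read_cluster_labels(path: str | Path) -> np.ndarray:
    """Read cluster labels from a TSV with columns ``cell_id``, ``cluster``."""
    df = pd.read_csv(path, sep="\t")
    if "cluster" not in df.columns:
        raise ValueError("cluster label file must have a 'cluster' column")
    return df["cluster"].to_numpy()
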