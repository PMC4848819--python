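"""Pooling and deconvolution of size factors.

The central idea: single-cell counts carry too many stochastic zeroes
for ratio-based normalization, but *sums* of counts over pools of cells
do not.  Each cell's counts are first divided by an adjustment factor
``t_j`` (its library size), pools of cells with similar library sizes
are summed, and each pooled profile is normalized against an averaged
reference pseudo-cell by a median of gene-wise ratios.  Because the
expectation of a pool's ratio equals the sum of its members'
``theta_j / t_j`` (up to one global constant), every pool yields one
linear equation in the per-cell unknowns.  Sliding windows of several
sizes around a ring of cells ordered by library size produce an
overdetermined system, which is solved by weighted least squares —
"deconvolving" pool factors into cell factors.  Low-weight per-cell
anchor equations guarantee full column rank, and a non-negative
re-solve guards against nonsensical negative factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import lstsq
from scipy.optimize import nnls

from ._matrix import CountMatrix, SizeFactorSet

__all__ = [
    "RingOrder",
    "Pool",
    "PoolSystem",
    "DeconvolutionResult",
    "ring_order",
    "define_pools",
    "pool_factor",
    "build_system",
    "solve_factors",
    "compute_sum_factors",
    "DEFAULT_WINDOW_SIZES",
]

DEFAULT_WINDOW_SIZES: tuple[int, ...] = (20, 40, 60, 80, 100)

#: Weight of the per-cell anchor equations relative to pool equations.
LOW_WEIGHT = 1e-6

#: Relative tolerance below which a least-squares estimate counts as negative.
SOLVER_TOL = 1e-10


@dataclass(frozen=True)
class RingOrder:
    """A circular arrangement of cell indices within one cluster.

    Cells are ranked by decreasing library size and laid out on a ring:
    the largest cell first, then the even ranks with decreasing size
    down to the smallest cell at the antipode, then the odd ranks
    climbing back up.  Consecutive ring positions therefore always hold
    cells of similar library size, so sliding windows form pools of
    comparable depth with no truncation at the boundaries.
    """

    sequence: np.ndarray

    def __post_init__(self) -> None:
        seq = np.asarray(self.sequence, dtype=np.intp)
        if sorted(seq.tolist()) != list(range(seq.size)):
            raise ValueError("ring sequence must be a permutation of 0..n-1")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return self.sequence.size


@dataclass
class Pool:
    """One pool of cells and (once estimated) its pooled size factor."""

    members: tuple[int, ...]
    window_size: int
    factor_estimate: float | None = None

    def __post_init__(self) -> None:
        if len(self.members) != self.window_size:
            raise ValueError("pool must contain exactly window_size members")


@dataclass
class PoolSystem:
    """The overdetermined weighted linear system in ``theta_j / t_j``.

    Pool rows (weight 1) say that the sum of the unknowns over a pool's
    members equals the pool's estimated factor.  Anchor rows (weight
    ``low_weight``) equate each cell's unknown to its own single-cell
    median-ratio estimate; they contribute negligibly to the solution
    but make the coefficient matrix full column rank.
    """

    pools: list[Pool]
    anchor_estimates: np.ndarray
    adjustment: np.ndarray          # t_j per cell
    reference_profile: np.ndarray   # u_i per gene
    low_weight: float = LOW_WEIGHT
    n_cells: int = field(init=False)

    def __post_init__(self) -> None:
        self.anchor_estimates = np.asarray(self.anchor_estimates, dtype=float)
        self.adjustment = np.asarray(self.adjustment, dtype=float)
        self.n_cells = self.adjustment.size
        if self.anchor_estimates.size != self.n_cells:
            raise ValueError("one anchor estimate per cell is required")
        if self.low_weight <= 0:
            raise ValueError("low_weight must be positive")
        covered = set()
        for p in self.pools:
            covered.update(p.members)
        if covered != set(range(self.n_cells)):
            raise ValueError("every cell must appear in at least one pool")

    def design(self) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
        """Stack pool and anchor rows into (A, b, weights)."""
        n = self.n_cells
        rows, cols = [], []
        for k, p in enumerate(self.pools):
            rows.extend([k] * len(p.members))
            cols.extend(p.members)
        a_pool = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(self.pools), n)
        )
        a = sp.vstack([a_pool, sp.identity(n, format="csr")], format="csr")
        b = np.concatenate(
            [[p.factor_estimate for p in self.pools], self.anchor_estimates]
        ).astype(float)
        w = np.concatenate([np.ones(len(self.pools)), np.full(n, self.low_weight)])
        return a, b, w


@dataclass
class DeconvolutionResult:
    """Deconvolved size factors plus bookkeeping on clamped cells."""

    factors: SizeFactorSet
    n_zero_factors: int = 0

    @property
    def zero_factor_mask(self) -> np.ndarray:
        return self.factors.factor == 0


def ring_order(library_sizes: np.ndarray) -> RingOrder:
    """Arrange cells on the library-size ring.

    Rank 1 (largest library) sits first; even ranks follow in
    increasing rank order (decreasing size), reaching the smallest
    library at the antipode; odd ranks >= 3 return in decreasing rank
    order (increasing size).  Ties are broken by input order (stable
    sort), so the result is deterministic.
    """
    lib = np.asarray(library_sizes, dtype=float)
    if lib.size == 0:
        raise ValueError("at least one cell is required")
    by_rank = np.argsort(-lib, kind="stable")  # by_rank[r-1] = cell with rank r
    n = lib.size
    evens = by_rank[1::2]          # ranks 2, 4, 6, ...
    odds_desc = by_rank[2::2][::-1]  # ranks ..., 7, 5, 3
    seq = np.concatenate([[by_rank[0]], evens, odds_desc]).astype(np.intp)
    return RingOrder(seq)


def define_pools(
    ring: RingOrder, window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
) -> list[Pool]:
    """Slide windows of each size around the ring, one pool per position.

    For every retained window size ``w`` there are exactly ``n`` pools
    (one per ring position, wrapping), and each cell belongs to exactly
    ``w`` of them.  Window sizes exceeding the ring length are dropped
    with a warning; if none survive, an error is raised.
    """
    n = len(ring)
    sizes = []
    for w in window_sizes:
        if w <= 0 or int(w) != w:
            raise ValueError(f"window size must be a positive integer, got {w!r}")
        if w > n:
            warnings.warn(
                f"window size {w} exceeds the number of cells ({n}) and is dropped",
                stacklevel=2,
            )
        else:
            sizes.append(int(w))
    if not sizes:
        raise ValueError("no window size fits the number of cells")
    seq = ring.sequence
    doubled = np.concatenate([seq, seq])
    pools = []
    for w in sizes:
        for i in range(n):
            pools.append(Pool(tuple(doubled[i : i + w].tolist()), w))
    return pools


def pool_factor(
    counts: CountMatrix,
    pool: Pool,
    adjustment: np.ndarray,
    reference_profile: np.ndarray,
) -> float:
    """Median ratio of a pool's summed adjusted profile to the reference.

    ``v_i = sum_{j in pool} y_ij / t_j`` is compared to the reference
    ``u_i`` gene by gene; the pool factor is the median of ``v_i / u_i``
    over genes with ``u_i > 0``.  Genes where the pooled sum is zero
    contribute a ratio of 0: a zero that survives summation over the
    whole pool is treated as real signal, unlike a single-cell zero.
    """
    t = np.asarray(adjustment, dtype=float)
    if np.any(t <= 0):
        raise ValueError("adjustment factors must be strictly positive")
    u = np.asarray(reference_profile, dtype=float)
    usable = u > 0
    if not usable.any():
        raise ValueError("reference profile has no strictly positive entries")
    members = list(pool.members)
    v = (counts.values[:, members] / t[members]).sum(axis=1)
    return float(np.median(v[usable] / u[usable]))


def _pooled_medians(
    z: np.ndarray, ring: RingOrder, sizes: list[int], u: np.ndarray
) -> list[Pool]:
    """Vectorized pool construction + factor estimation for all windows."""
    usable = u > 0
    n = z.shape[1]
    z_ring = z[:, ring.sequence]
    csum = np.concatenate(
        [np.zeros((z.shape[0], 1)), np.cumsum(np.hstack([z_ring, z_ring]), axis=1)],
        axis=1,
    )
    doubled = np.concatenate([ring.sequence, ring.sequence])
    pools: list[Pool] = []
    for w in sizes:
        v = csum[:, w : w + n] - csum[:, :n]  # pooled profile per start position
        r = v[usable, :] / u[usable, None]
        med = np.median(r, axis=0)
        for i in range(n):
            pools.append(
                Pool(tuple(doubled[i : i + w].tolist()), w, float(med[i]))
            )
    return pools


def _anchor_estimates(z: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Single-cell median-ratio estimates of ``theta_j / t_j``.

    Ratios of zero are removed before the median (the same workaround
    the median-of-ratios baseline needs); a cell with no usable ratios
    gets an anchor of 1.  These only feed the low-weight anchor rows.
    """
    usable = u > 0
    ratios = z[usable, :] / u[usable, None]
    out = np.empty(z.shape[1])
    for j in range(z.shape[1]):
        rj = ratios[:, j]
        rj = rj[rj > 0]
        out[j] = np.median(rj) if rj.size else 1.0
    return out


def build_system(
    counts: CountMatrix,
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
    adjustment: np.ndarray | str = "library_size",
    low_weight: float = LOW_WEIGHT,
    ring: RingOrder | None = None,
) -> PoolSystem:
    """Assemble the weighted linear system for one cluster of cells.

    The adjustment ``t_j`` defaults to the observed library size, which
    stops large libraries from dominating pooled sums and equalizes
    each cell's influence on the pool medians.  The reference profile
    ``u_i`` is the mean of ``y_ij / t_j`` across all cells (the
    averaged pseudo-cell).
    """
    if counts.n_cells < 2:
        raise ValueError("deconvolution requires at least 2 cells")
    lib = counts.library_sizes().astype(float)
    if np.any(lib == 0):
        j = int(np.argmin(lib))
        raise ValueError(f"cell {counts.cell_ids[j]!r} has a total count of zero")
    if isinstance(adjustment, str):
        if adjustment != "library_size":
            raise ValueError(f"unknown adjustment mode {adjustment!r}")
        t = lib
    else:
        t = np.asarray(adjustment, dtype=float)
        if t.shape != (counts.n_cells,) or np.any(t <= 0):
            raise ValueError("explicit adjustment must be positive, one value per cell")

    z = counts.values / t
    u = z.mean(axis=1)
    if ring is None:
        ring = ring_order(lib)
    n = counts.n_cells
    sizes = [int(w) for w in window_sizes if 0 < w <= n]
    dropped = [w for w in window_sizes if w > n]
    if dropped:
        warnings.warn(
            f"window sizes {dropped} exceed the number of cells ({n}) and are dropped",
            stacklevel=2,
        )
    if not sizes:
        raise ValueError("no window size fits the number of cells")

    pools = _pooled_medians(z, ring, sizes, u)
    anchors = _anchor_estimates(z, u)
    return PoolSystem(pools, anchors, t, u, low_weight)


def solve_factors(system: PoolSystem, center: bool = True) -> DeconvolutionResult:
    """Solve the weighted system and convert estimates into size factors.

    The fast path solves the weighted normal equations directly.  If
    any estimate comes out negative, the system is re-solved under
    non-negativity constraints; cells pinned at zero are flagged (and
    should be discarded by the caller as likely low-quality libraries)
    rather than silently dropped.  Standard errors come from a sandwich
    covariance around the weighted normal equations (see inline note),
    propagated through the multiplication by ``t_j``; clamped cells get
    no standard error.  Factors are returned centered to mean 1 over
    the positive entries.
    """
    a, b, w = system.design()
    n = system.n_cells
    sw = np.sqrt(w)
    a_dense = a.toarray() * sw[:, None]
    # QR-based solve on the weighted rows: the normal equations square the
    # condition number of the pool blocks and lose too much accuracy
    est = lstsq(a_dense, b * sw)[0]

    clamped = np.zeros(n, dtype=bool)
    if np.any(est < -SOLVER_TOL * max(1.0, np.abs(est).max())):
        est, _ = nnls(a_dense, b * sw)
        clamped = est <= 0
        est = np.where(clamped, 0.0, est)
    else:
        est = np.maximum(est, 0.0)
        clamped = est == 0

    if not np.any(est > 0):
        raise ValueError("deconvolution produced an all-zero solution")

    resid = b - a @ est
    n_pool = len(system.pools)
    se = None
    if a.shape[0] > n and n_pool > n:
        # Sandwich covariance with separate residual variances for pool and
        # anchor rows.  The classical WLS formula sigma^2 (A'WA)^-1 treats the
        # anchor weights as inverse variances, which blows up the variance of
        # the near-null modes of the pool blocks (even window sizes leave an
        # alternating mode that only the anchors pin down) far beyond the
        # anchors' actual noise.  Estimating each row class's variance from
        # its own residuals keeps the uncertainty honest.
        sig_pool = float(np.sum(resid[:n_pool] ** 2) / (n_pool - n))
        sig_anchor = float(np.mean(resid[n_pool:] ** 2))
        bread = np.linalg.inv(a_dense.T @ a_dense)
        ap = a[:n_pool].toarray()
        meat = sig_pool * (ap.T @ ap) + sig_anchor * system.low_weight**2 * np.eye(n)
        cov = bread @ meat @ bread
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None)) * system.adjustment
        se[clamped] = np.nan

    factors = est * system.adjustment
    sfs = SizeFactorSet(factors, std_error=se)
    if center:
        sfs = sfs.centered("mean_one")
    return DeconvolutionResult(sfs, n_zero_factors=int(clamped.sum()))


def _random_ring(n: int, rng: np.random.Generator) -> RingOrder:
    """Random cell arrangement: windows over it give random pools of each size."""
    return RingOrder(rng.permutation(n))


def compute_sum_factors(
    counts: CountMatrix,
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
    clusters: np.ndarray | None = None,
    min_mean: float | None = None,
    pool_strategy: str = "ring",
    seed: int | None = None,
) -> DeconvolutionResult:
    """Pool-and-deconvolve size factors for a whole dataset.

    Without ``clusters`` the linear system is built over all cells at
    once.  With cluster labels, deconvolution runs within each cluster
    against a cluster-specific pseudo-cell, and the per-cluster factors
    are made comparable by normalizing the pseudo-cells against a
    baseline cluster (see :func:`pooldeconv.clustering.rescale_clusters`).
    Window sizes larger than a cluster are dropped for that cluster with
    a warning.

    Parameters
    ----------
    min_mean
        If given, genes with mean count below this are excluded before
        building the system (low-abundance genes carry mostly noise
        into the ratio medians).
    pool_strategy
        ``"ring"`` (default) slides windows over the library-size ring;
        ``"random"`` slides them over a randomly permuted arrangement,
        producing random pools of the same sizes (useful for assessing
        the benefit of the ring; requires ``seed``).
    """
    if pool_strategy not in ("ring", "random"):
        raise ValueError(f"unknown pool_strategy {pool_strategy!r}")
    rng = np.random.default_rng(seed) if pool_strategy == "random" else None

    work = counts
    if min_mean is not None:
        keep = work.values.mean(axis=1) >= min_mean
        if not keep.any():
            raise ValueError("no genes left after the abundance filter")
        work = work.subset_genes(keep)

    if clusters is None:
        ring = _random_ring(work.n_cells, rng) if rng is not None else None
        system = build_system(work, window_sizes, ring=ring)
        result = solve_factors(system)
        result.factors.cell_ids = list(counts.cell_ids)
        return result

    labels = np.asarray(clusters)
    if labels.shape != (counts.n_cells,):
        raise ValueError("clusters must provide one label per cell")
    # deferred import: clustering depends on this module's solver
    from .clustering import rescale_clusters

    uniq = list(dict.fromkeys(labels.tolist()))  # stable order of appearance
    per_cluster_sets, pseudo_cells, index_groups = [], [], []
    min_w = min(window_sizes)
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_w:
            raise ValueError(
                f"cluster {lab!r} has {idx.size} cells, fewer than the smallest "
                f"window size {min_w}"
            )
        sub = work.subset_cells(idx)
        ring = _random_ring(sub.n_cells, rng) if rng is not None else None
        system = build_system(sub, window_sizes, ring=ring)
        # raw (uncentered) factors keep their scale relative to the cluster
        # pseudo-cell; the tau rescaling below relies on that
        res = solve_factors(system, center=False)
        per_cluster_sets.append(res.factors)
        pseudo_cells.append(system.reference_profile)
        index_groups.append(idx)

    merged = rescale_clusters(per_cluster_sets, pseudo_cells)
    factor = np.empty(counts.n_cells)
    se = np.full(counts.n_cells, np.nan)
    have_se = all(s.std_error is not None for s in merged)
    for sfs, idx in zip(merged, index_groups):
        factor[idx] = sfs.factor
        if sfs.std_error is not None:
            se[idx] = sfs.std_error
    final = SizeFactorSet(
        factor, counts.cell_ids, se if have_se else None, centering="raw"
    ).centered("mean_one")
    return DeconvolutionResult(final, n_zero_factors=int((factor == 0).sum()))
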