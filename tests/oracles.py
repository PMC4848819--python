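"""Independent brute-force reference implementations used only by tests.

Each oracle follows the written definition of its operation as directly
as possible (explicit loops, no shared code with the package) so it can
serve as a second, independent route to the same numbers.
"""

import math

import numpy as np


def median_ratio_oracle(values: np.ndarray) -> np.ndarray:
    """Median-of-ratios factors by direct enumeration, mean-centered."""
    n_genes, n_cells = values.shape
    refs = []
    for i in range(n_genes):
        nz = [v for v in values[i] if v > 0]
        refs.append(math.exp(sum(math.log(v) for v in nz) / len(nz)) if nz else None)
    factors = []
    for j in range(n_cells):
        ratios = sorted(
            values[i, j] / refs[i]
            for i in range(n_genes)
            if refs[i] is not None and values[i, j] > 0
        )
        m = len(ratios)
        if m == 0:
            factors.append(0.0)
        elif m % 2:
            factors.append(ratios[m // 2])
        else:
            factors.append(0.5 * (ratios[m // 2 - 1] + ratios[m // 2]))
    factors = np.array(factors)
    return factors / factors[factors > 0].mean()


def _rank_average(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(values: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """TMM effective-library-size factors by explicit enumeration, mean-centered."""
    n_genes, n_cells = values.shape
    totals = values.sum(axis=0).astype(float)
    q75 = [np.quantile(values[:, j], 0.75) / totals[j] for j in range(n_cells)]
    mean_q = sum(q75) / n_cells
    ref = min(range(n_cells), key=lambda j: abs(q75[j] - mean_q))

    nf = []
    for j in range(n_cells):
        if j == ref:
            nf.append(1.0)
            continue
        m_vals, a_vals, weights = [], [], []
        for i in range(n_genes):
            yo, yr = values[i, j], values[i, ref]
            if yo > 0 and yr > 0:
                po, pr = yo / totals[j], yr / totals[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * math.log2(po * pr))
                weights.append(
                    1.0
                    / (
                        (totals[j] - yo) / (totals[j] * yo)
                        + (totals[ref] - yr) / (totals[ref] * yr)
                    )
                )
        if max(abs(m) for m in m_vals) < 1e-6:
            nf.append(1.0)
            continue
        n = len(m_vals)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = _rank_average(m_vals)
        ra = _rank_average(a_vals)
        num = den = 0.0
        for k in range(n):
            if lo_m <= rm[k] <= hi_m and lo_a <= ra[k] <= hi_a:
                num += weights[k] * m_vals[k]
                den += weights[k]
        nf.append(2.0 ** (num / den))
    nf = np.array(nf)
    nf = nf / math.exp(np.mean(np.log(nf)))
    sf = nf * totals
    return sf / sf.mean()


def pool_factor_oracle(values, members, t, u):
    """Median over u>0 genes of the pooled adjusted sum over the reference."""
    ratios = []
    for i in range(values.shape[0]):
        if u[i] > 0:
            v = sum(values[i, j] / t[j] for j in members)
            ratios.append(v / u[i])
    return float(np.median(ratios))


def wls_oracle(pools, pool_responses, anchors, low_weight, n_cells):
    """Dense weighted least-squares solve of the pool system via lstsq."""
    rows = []
    b = []
    w = []
    for members, resp in zip(pools, pool_responses):
        row = np.zeros(n_cells)
        row[list(members)] = 1.0
        rows.append(row)
        b.append(resp)
        w.append(1.0)
    for j in range(n_cells):
        row = np.zeros(n_cells)
        row[j] = 1.0
        rows.append(row)
        b.append(anchors[j])
        w.append(low_weight)
    a = np.array(rows)
    b = np.array(b)
    sw = np.sqrt(np.array(w))
    sol, *_ = np.linalg.lstsq(a * sw[:, None], b * sw, rcond=None)
    return sol


def nnls_oracle(pools, pool_responses, anchors, low_weight, n_cells):
    """Bounded least squares via scipy's bvls (independent of the nnls path)."""
    from scipy.optimize import lsq_linear

    rows, b, w = [], [], []
    for members, resp in zip(pools, pool_responses):
        row = np.zeros(n_cells)
        row[list(members)] = 1.0
        rows.append(row)
        b.append(resp)
        w.append(1.0)
    for j in range(n_cells):
        row = np.zeros(n_cells)
        row[j] = 1.0
        rows.append(row)
        b.append(anchors[j])
        w.append(low_weight)
    a = np.array(rows)
    sw = np.sqrt(np.array(w))
    res = lsq_linear(a * sw[:, None], np.array(b) * sw, bounds=(0, np.inf), method="bvls")
    return res.x


def running_median_oracle(cv2_sorted, window):
    """Sliding median over a fixed-width window clamped at the edges."""
    n = len(cv2_sorted)
    half = window // 2
    out = []
    for pos in range(n):
        lo = max(0, min(pos - half, n - window))
        out.append(float(np.median(cv2_sorted[lo : lo + window])))
    return np.array(out)
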