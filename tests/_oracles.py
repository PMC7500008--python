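"""Independent straight-line oracles used to verify the package's statistics.

Everything here is deliberately written in the most literal way available —
explicit enumeration, exact rational arithmetic, plain loops — and shares no
code path with the implementations it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def mw_u_naive(x, y):
    """U = #{x_i > y_j} + 0.5 #{ties}, by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_enum_p(x, y):
    """Exact two-sided Mann–Whitney p by full enumeration of labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mw_u_naive(x, y)
    lo = hi = total = 0
    for subset in combinations(range(len(pooled)), n1):
        in_x = set(subset)
        xs = [pooled[i] for i in range(len(pooled)) if i in in_x]
        ys = [pooled[i] for i in range(len(pooled)) if i not in in_x]
        u = mw_u_naive(xs, ys)
        total += 1
        if u <= u_obs + 1e-12:
            lo += 1
        if u >= u_obs - 1e-12:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def fisher_enum_p(table):
    """Two-sided Fisher p by explicit hypergeometric enumeration (exact rationals).

    Sums the probabilities of every table with the observed margins whose
    point probability does not exceed the observed one (1 + 1e-7 tolerance).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return None
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = point_prob(a)
    cutoff = p_obs * (Fraction(10**7 + 1, 10**7))
    total = Fraction(0)
    for k in range(0, min(r1, c1) + 1):
        p = point_prob(k)
        if p is not None and p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


def bh_step_up(pvals):
    """Literal BH step-up: q_(i) = min_{j >= i} p_(j) * n / j, input order."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q_sorted = [0.0] * n
    for rank_pos in range(n):
        candidates = []
        for j in range(rank_pos, n):
            candidates.append(p[order[j]] * n / (j + 1))
        q_sorted[rank_pos] = min(1.0, min(candidates))
    q = [0.0] * n
    for rank_pos, idx in enumerate(order):
        q[idx] = q_sorted[rank_pos]
    return q


def _average_ranks(values):
    """Mid-ranks (1-based, ties averaged), by explicit sorting."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # average of 1-based positions i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(counts, trim_m=0.30, trim_a=0.05, ref_idx=None):
    """Straight-line TMM factors (geometric mean 1) on an integer matrix."""
    counts = [list(map(float, row)) for row in counts]
    n_mirnas = len(counts)
    n_samples = len(counts[0])
    totals = [sum(counts[m][s] for m in range(n_mirnas)) for s in range(n_samples)]
    if ref_idx is None:
        q75 = []
        for s in range(n_samples):
            col = sorted(counts[m][s] / totals[s] for m in range(n_mirnas))
            # linear-interpolation quantile, matching numpy's default
            h = (n_mirnas - 1) * 0.75
            lo = int(h)
            frac = h - lo
            q = col[lo] + frac * (col[min(lo + 1, n_mirnas - 1)] - col[lo])
            q75.append(q)
        mean_q = sum(q75) / n_samples
        ref_idx = min(range(n_samples), key=lambda s: abs(q75[s] - mean_q))
    factors = []
    for s in range(n_samples):
        if s == ref_idx:
            factors.append(1.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for m in range(n_mirnas):
            x, r = counts[m][s], counts[m][ref_idx]
            if x > 0 and r > 0:
                px, pr = x / totals[s], r / totals[ref_idx]
                m_vals.append(np.log2(px / pr))
                a_vals.append(0.5 * np.log2(px * pr))
                w_vals.append(
                    (totals[s] - x) / (totals[s] * x)
                    + (totals[ref_idx] - r) / (totals[ref_idx] * r)
                )
        if max(abs(v) for v in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        k = len(m_vals)
        rank_m = _average_ranks(m_vals)
        rank_a = _average_ranks(a_vals)
        lo_m, hi_m = int(k * trim_m) + 1, k - int(k * trim_m)
        lo_a, hi_a = int(k * trim_a) + 1, k - int(k * trim_a)
        num = den = 0.0
        for i in range(k):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        factors.append(2.0 ** (num / den))
    log_mean = sum(np.log(f) for f in factors) / n_samples
    return [f / np.exp(log_mean) for f in factors]


def rle_oracle(counts):
    """Straight-line median-ratio (RLE) factors, geometric mean 1."""
    counts = [list(map(float, row)) for row in counts]
    n_mirnas = len(counts)
    n_samples = len(counts[0])
    totals = [sum(counts[m][s] for m in range(n_mirnas)) for s in range(n_samples)]
    rows = [m for m in range(n_mirnas) if all(counts[m][s] > 0 for s in range(n_samples))]
    sizes = []
    for s in range(n_samples):
        ratios = []
        for m in rows:
            gm = np.exp(sum(np.log(counts[m][t]) for t in range(n_samples)) / n_samples)
            ratios.append(counts[m][s] / gm)
        ratios.sort()
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        sizes.append(med / totals[s])
    log_mean = sum(np.log(f) for f in sizes) / n_samples
    return [f / np.exp(log_mean) for f in sizes]


def spearman_oracle(x, y):
    """Spearman r from hand-computed mid-ranks and the Pearson formula."""
    rx = _average_ranks(list(x))
    ry = _average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((rx[i] - mx) * (ry[i] - my) for i in range(n))
    den = (
        sum((rx[i] - mx) ** 2 for i in range(n))
        * sum((ry[i] - my) ** 2 for i in range(n))
    ) ** 0.5
    return num / den
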