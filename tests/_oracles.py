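"""Independent oracles used by the test suite.

Deliberately naive implementations (enumeration, brute force, textbook
formulas) that never share code with the package under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist


def yates_chi2_p(table) -> float:
    """Textbook 2x2 chi-square with Yates continuity correction."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    num = max(0.0, abs(a * d - b * c) - n / 2.0) ** 2 * n
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return float(chi2_dist.sf(num / den, 1))


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher exact p by exact hypergeometric enumeration
    (all tables with probability <= the observed one, exact rationals)."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up, written out directly."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out


def brute_force_pair_count(xy_a, ids_a, xy_b, ids_b, r, same_type=False) -> int:
    """O(mn) double-loop interacting-pair count."""
    xy_a, xy_b = np.asarray(xy_a, float), np.asarray(xy_b, float)
    count = 0
    if same_type:
        for j in range(len(ids_a)):
            for k in range(j + 1, len(ids_a)):
                if np.hypot(*(xy_a[j] - xy_a[k])) <= r:
                    count += 1
        return count
    for j in range(len(ids_a)):
        for k in range(len(ids_b)):
            if ids_a[j] == ids_b[k]:
                continue
            if np.hypot(*(xy_a[j] - xy_b[k])) <= r:
                count += 1
    return count


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration (no ties assumed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def ustat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = ustat(x, y)
    hits = total = 0
    idx = range(n1 + n2)
    for chosen in combinations(idx, n1):
        s = set(chosen)
        xs = pooled[list(chosen)]
        ys = pooled[[i for i in idx if i not in s]]
        total += 1
        if abs(ustat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def best_two_split_by_ss(values) -> np.ndarray:
    """Optimal 1-D two-cluster partition minimizing total within-cluster sum
    of squares (contiguous in sorted order); returns the upper-cluster mask."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v)
    sv = v[order]
    best_cut, best_ss = None, np.inf
    for cut in range(1, len(sv)):
        left, right = sv[:cut], sv[cut:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ss < best_ss:
            best_ss, best_cut = ss, cut
    mask = np.zeros(len(v), dtype=bool)
    mask[order[best_cut:]] = True
    return mask
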