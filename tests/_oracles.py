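"""Independent brute-force oracles shared by test modules.

These deliberately re-derive null distributions by direct enumeration
(itertools + exact arithmetic) so they share no code path with the
package implementations they check.
"""

import math
from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def brute_mann_whitney(x, y, alternative):
    """Full enumeration of group assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(a, b):
        return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0
                   for ai in a for bi in b)

    u_obs = u_of(x, y)
    ge = le = tot = 0
    for idx in combinations(range(len(pooled)), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = u_of(xs, ys)
        tot += 1
        ge += u >= u_obs - 1e-9
        le += u <= u_obs + 1e-9
    if alternative == "greater":
        return u_obs, ge / tot
    if alternative == "less":
        return u_obs, le / tot
    return u_obs, min(1.0, 2.0 * min(ge, le) / tot)


def brute_wilcoxon_vs_half(ranks, alternative):
    """Enumerate all sign flips of the nonzero differences from 0.5."""
    d = [r - 0.5 for r in ranks if r != 0.5]
    m = len(d)
    r = rankdata(np.abs(d))
    w_obs = sum(ri for ri, di in zip(r, d) if di > 0)
    ge = le = tot = 0
    for signs in product([0, 1], repeat=m):
        w = sum(ri for ri, s in zip(r, signs) if s)
        tot += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if alternative == "greater":
        return w_obs, ge / tot
    if alternative == "less":
        return w_obs, le / tot
    return w_obs, min(1.0, 2.0 * min(ge, le) / tot)


def brute_het_distribution(k, n, s=0.0, triple=None):
    """Conditional heterozygote-count distribution by explicit enumeration."""
    if triple is None:
        triple = (1.0, 1.0 + s, 1.0)
    wAA, wH, wDD = triple
    if k == 0 or k == 2 * n:
        return {0: 1.0}
    p = k / (2 * n)
    q = 1 - p
    weights = {}
    for h in range(k % 2, min(k, 2 * n - k) + 1, 2):
        n_dd = (k - h) // 2
        n_aa = n - h - n_dd
        coeff = math.comb(n, h) * math.comb(n - h, n_dd)
        weights[h] = coeff * (p * p * wDD) ** n_dd * (2 * p * q * wH) ** h \
            * (q * q * wAA) ** n_aa
    total = sum(weights.values())
    return {h: w / total for h, w in weights.items()}
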