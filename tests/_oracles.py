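"""Brute-force enumeration oracles for the rank tests.

Independent of the implementation under test: ranks come straight from
scipy and the null distributions from explicit enumeration.
"""

from itertools import combinations, product

import numpy as np
from scipy import stats as sps


def wilcoxon_enumeration_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(nz))
    n = len(nz)
    w_obs = ranks[nz > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def mannwhitney_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * len(b) / 2.0
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def kruskal_enumeration_p(groups):
    """Exact permutation p of tie-corrected H over all group assignments."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)

    def h_of(rank_groups):
        h = sum(len(g) * g.mean() ** 2 for g in rank_groups)
        return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)

    bounds = np.cumsum([0] + sizes)
    h_obs = h_of([ranks[bounds[i]: bounds[i + 1]] for i in range(len(sizes))])
    count = total = 0

    def assignments(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        for combo in combinations(remaining, sizes_left[0]):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in assignments(rest, sizes_left[1:]):
                yield [combo] + tail

    for groups_idx in assignments(tuple(range(n)), sizes):
        total += 1
        if h_of([ranks[list(g)] for g in groups_idx]) >= h_obs - 1e-9:
            count += 1
    return count / total
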