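"""Nonparametric comparisons for perfusion parameter tables.

Paired contrasts (e.g. pixel-wise vs ROI-based parameters on the same
vertebrae) use the Wilcoxon signed-rank test; unpaired two-group contrasts
(e.g. aortic vs segmental AIF SNR) the Mann-Whitney U test; multi-group
contrasts the Kruskal-Wallis test with Dunn pairwise z-tests under
Bonferroni correction.

Small samples get exact null distributions (signed-rank and rank-sum by
dynamic programming over doubled midranks; Kruskal-Wallis by exhaustive
enumeration of group assignments), larger ones tie-corrected normal /
chi-square approximations.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .exceptions import InvalidParameterError

__all__ = ["ComparisonReport", "compare_paired", "compare_unpaired",
           "compare_groups"]

EXACT_N_MAX = 12  # exact-null threshold (total observations)


@dataclass
class ComparisonReport:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    n_per_group: tuple
    group_labels: tuple = ()
    pairwise: dict | None = None  # (i, j) -> {z, p_unadjusted, p_adjusted}
    exact: bool = False
    degenerate: bool = False

    def __post_init__(self):
        self.p_value = float(min(max(self.p_value, 0.0), 1.0))


def _midranks(x):
    return sps.rankdata(x, method="average")


def _signed_rank_exact_p(dranks, w2_obs):
    """Two-sided exact p for the signed-rank statistic.

    ``dranks``: doubled midranks of |differences| (integers even with
    midrank ties).  DP over the distribution of the doubled positive-rank
    sum W2+; two-sided p sums the tail symmetric about the null mean.
    """
    total = int(sum(dranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in dranks:
        r = int(round(r))
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    mu = total / 2.0
    dev = abs(w2_obs - mu)
    w = np.arange(total + 1)
    p = counts[np.abs(w - mu) >= dev - 1e-9].sum() / counts.sum()
    return float(min(p, 1.0))


def compare_paired(a, b) -> ComparisonReport:
    """Wilcoxon signed-rank test on paired samples (two-sided).

    Zero differences are dropped (Wilcoxon's rule); if every difference is
    zero the comparison is degenerate and p = 1 is reported with a flag.
    Exact distribution for n <= 12 non-zero pairs, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired samples must have equal length")
    if len(a) < 5:
        raise InvalidParameterError("paired test needs n >= 5")
    d = a - b
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return ComparisonReport("wilcoxon_signed_rank", 0.0, 1.0,
                                (len(a),), degenerate=True)
    ranks = _midranks(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    if n <= EXACT_N_MAX:
        dranks = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(dranks, 2 * w_plus)
        return ComparisonReport("wilcoxon_signed_rank", float(w_plus), p,
                                (len(a),), exact=True)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonReport("wilcoxon_signed_rank", float(w_plus), p, (len(a),))


def _rank_sum_exact_p(ranks_all, n1, u_obs):
    """Two-sided exact p for Mann-Whitney U by subset-sum DP.

    Counts subsets of size n1 of the pooled (doubled) midranks by their
    rank sum; valid with ties because the DP runs on the actual ranks.
    """
    dranks = np.round(2 * np.asarray(ranks_all)).astype(int)
    total = int(dranks.sum())
    # counts[k, s]: subsets of size k with doubled-rank sum s
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for r in dranks:
        counts[1:, r:] += counts[:-1, : total + 1 - r]
    dist = counts[n1]
    n2 = len(dranks) - n1
    # doubled rank sum -> doubled U: 2U = 2R1 - n1(n1+1)
    s = np.arange(total + 1)
    u2 = s - n1 * (n1 + 1)
    mu2 = n1 * n2  # doubled null mean of U
    dev = abs(2 * u_obs - mu2)
    sel = np.abs(u2 - mu2) >= dev - 1e-9
    return float(min(dist[sel].sum() / dist.sum(), 1.0))


def compare_unpaired(a, b) -> ComparisonReport:
    """Mann-Whitney U test on two independent samples (two-sided).

    Exact null for combined n <= 12, tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InvalidParameterError("unpaired test needs n >= 3 per group")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= EXACT_N_MAX:
        p = _rank_sum_exact_p(ranks, n1, u)
        return ComparisonReport("mann_whitney_u", float(u), p, (n1, n2),
                                exact=True)
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonReport("mann_whitney_u", float(u), p, (n1, n2))


def _kw_h_raw(rank_groups, n):
    """Uncorrected Kruskal-Wallis H from per-group midranks."""
    h = sum(len(g) * g.mean() ** 2 for g in rank_groups)
    return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)


def _kw_tie_correction(ranks):
    n = len(ranks)
    _, tie_counts = np.unique(ranks, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction <= 0:
        raise InvalidParameterError("all observations tied")
    return correction


def _kw_h(ranks, sizes):
    """Tie-corrected Kruskal-Wallis H from pooled midranks split by group."""
    groups = []
    start = 0
    for m in sizes:
        groups.append(ranks[start: start + m])
        start += m
    return _kw_h_raw(groups, len(ranks)) / _kw_tie_correction(ranks)


def _kw_exact_p(ranks, sizes, h_obs):
    """Exact permutation p of H: enumerate distinct group assignments.

    The tie correction depends only on the pooled ranks, hence is
    permutation-invariant; uncorrected H values compare equivalently.
    """
    n = len(ranks)
    h_raw_obs = h_obs * _kw_tie_correction(ranks)
    count = 0
    total = 0
    stack = [(tuple(range(n)), list(sizes), [])]
    while stack:
        remaining, sizes_left, chosen = stack.pop()
        if not sizes_left:
            rank_groups = [ranks[list(g)] for g in chosen]
            total += 1
            if _kw_h_raw(rank_groups, n) >= h_raw_obs - 1e-12:
                count += 1
            continue
        m = sizes_left[0]
        for combo in combinations(remaining, m):
            rest = tuple(i for i in remaining if i not in combo)
            stack.append((rest, sizes_left[1:], chosen + [combo]))
    return count / total


def compare_groups(groups, labels=None) -> ComparisonReport:
    """Kruskal-Wallis omnibus test with Dunn-Bonferroni pairwise post hocs.

    Two groups delegate to the Mann-Whitney test.  The omnibus p is exact
    (permutation enumeration) for total n <= 12, chi-square otherwise.
    Pairwise Dunn z-tests use the pooled-rank variance with tie correction;
    their p-values are Bonferroni-multiplied by the number of pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if len(groups) == 2:
        return compare_unpaired(groups[0], groups[1])
    for g in groups:
        if len(g) < 2:
            raise InvalidParameterError("every group needs n >= 2")
    labels = tuple(labels) if labels else tuple(range(len(groups)))
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    if np.all(pooled == pooled[0]):
        pairwise = {
            (labels[i], labels[j]): {"z": 0.0, "p_unadjusted": 1.0,
                                     "p_adjusted": 1.0}
            for i, j in combinations(range(len(groups)), 2)
        }
        return ComparisonReport("kruskal_wallis", 0.0, 1.0, sizes, labels,
                                pairwise=pairwise, degenerate=True)
    h = _kw_h(ranks, sizes)
    exact = n <= EXACT_N_MAX
    if exact:
        p = _kw_exact_p(ranks, sizes, h)
    else:
        p = float(sps.chi2.sf(h, len(groups) - 1))

    # Dunn pairwise z-tests on mean ranks
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for m in sizes:
        mean_ranks.append(ranks[start: start + m].mean())
        start += m
    n_pairs = comb(len(groups), 2)
    pairwise = {}
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_un = float(2.0 * sps.norm.sf(abs(z)))
        pairwise[(labels[i], labels[j])] = {
            "z": float(z),
            "p_unadjusted": p_un,
            "p_adjusted": float(min(1.0, n_pairs * p_un)),
        }
    return ComparisonReport("kruskal_wallis", float(h), p, sizes, labels,
                            pairwise=pairwise, exact=exact)
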