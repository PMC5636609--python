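"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy's test machinery: p-values come from
exhaustive enumeration of all equally likely rank arrangements under
the null, so they can certify the exact modes of the package's KS and
Mann-Whitney wrappers on small samples.
"""

from itertools import combinations

import numpy as np


def ks_statistic(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by direct evaluation at all data points."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_exact_p(a, b) -> float:
    """P(D >= observed) enumerated over all C(n_a+n_b, n_a) label splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d_obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n = pooled.size
    idx = range(n)
    hits = total = 0
    for comb in combinations(idx, a.size):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        d = ks_statistic(pooled[mask], pooled[~mask])
        hits += d >= d_obs - 1e-12
        total += 1
    return hits / total


def mw_u(a, b) -> float:
    """Mann-Whitney U for sample a (count of a-over-b wins, ties 0.5)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mw_exact_p(a, b) -> float:
    """Two-tailed exact Mann-Whitney p by enumeration.

    The null distribution of U is symmetric about n_a*n_b/2, so the
    two-tailed p is the probability of a U at least as far from the
    center as observed.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    u_obs = mw_u(a, b)
    center = a.size * b.size / 2.0
    pooled = np.concatenate([a, b])
    n = pooled.size
    hits = total = 0
    for comb in combinations(range(n), a.size):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        u = mw_u(pooled[mask], pooled[~mask])
        hits += abs(u - center) >= abs(u_obs - center) - 1e-12
        total += 1
    return hits / total
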