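"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: exhaustive grid
search over exposure space for NNLS checks, and full enumeration of rank
assignments for the rank-sum test.
"""

import itertools

import numpy as np


def grid_search_2sig(catalog, profiles, hi=600, step=1):
    """Exhaustive least-squares search over an (a, b) exposure grid."""
    g = np.arange(0, hi + 1, step, dtype=float)
    P0, P1 = profiles[:, 0], profiles[:, 1]
    c0, c1 = catalog @ P0, catalog @ P1
    p00, p11, p01 = P0 @ P0, P1 @ P1, P0 @ P1
    aa, bb = np.meshgrid(g, g, indexing="ij")
    obj = -2 * aa * c0 - 2 * bb * c1 + aa**2 * p00 + 2 * aa * bb * p01 + bb**2 * p11
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    return g[i], g[j]


def grid_search_3sig(catalog, profiles, hi=600, step=5):
    """Exhaustive least-squares search over an (a, b, c) exposure grid."""
    g = np.arange(0, hi + 1, step, dtype=float)
    cP = catalog @ profiles
    G = profiles.T @ profiles
    x = g[:, None, None]
    y = g[None, :, None]
    z = g[None, None, :]
    obj = (
        -2 * (x * cP[0] + y * cP[1] + z * cP[2])
        + x**2 * G[0, 0] + y**2 * G[1, 1] + z**2 * G[2, 2]
        + 2 * x * y * G[0, 1] + 2 * x * z * G[0, 2] + 2 * y * z * G[1, 2]
    )
    idx = np.unravel_index(np.argmin(obj), obj.shape)
    return np.array([g[idx[0]], g[idx[1]], g[idx[2]]])


def rank_sum_p_greater(a, b):
    """Exact one-sided ('greater') rank-sum p by full enumeration."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    stat = sum(ranks[v] for v in a)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        s = sum(ranks[pooled[i]] for i in comb)
        total += 1
        if s >= stat:
            count += 1
    return count / total
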