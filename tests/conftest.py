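"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: sample
entropy is recomputed by naive O(N^2) template counting, and the exact
Mann-Whitney p-value by literal enumeration of all group labelings.
"""

from itertools import combinations
import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def naive_sample_entropy(series, m, tol):
    """Brute-force template counting (Chebyshev distance, <= tol,
    self-matches excluded, N-m templates for both lengths)."""
    x = np.asarray(series, dtype=float)
    n_t = x.size - m
    b = a = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    if a == 0 or b == 0:
        return float("nan"), b, a
    return -math.log(a / b), b, a


def enumerate_mann_whitney(a, b):
    """Exact two-sided p by enumerating every C(n1+n2, n1) labeling.

    U is the mid-rank U of the first group; the two-sided p doubles the
    smaller tail of the permutation distribution of U, capped at 1.
    """
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = []
    for idx in combinations(range(pooled.size), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
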