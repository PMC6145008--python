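"""Group-level statistics: exact Mann-Whitney U and Spearman correlation.

The Mann-Whitney test is exact by default for small samples: the null
distribution of the rank sum is built by a count recursion over all
C(n1+n2, n1) labelings of the pooled mid-ranks, which handles ties
correctly.  For larger samples the tie-corrected normal approximation is
used and flagged ``exact=False``; the z statistic is reported in both
regimes so either convention can be compared.  Two-sided p-values double
the smaller one-sided exact tail, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "StatsError", "ConstantInputError", "mann_whitney_exact", "spearman"]

#: Largest pooled sample for which the exact rank-sum enumeration runs by
#: default; the count recursion is cheap well beyond the ~25 where naive
#: enumeration of labelings stops being.
EXACT_MW_LIMIT = 30


class StatsError(ValueError):
    """Invalid input to a statistical test."""


class ConstantInputError(StatsError):
    """Correlation undefined because one input is constant."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or correlation test."""

    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    exact: bool
    z: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


def _ranksum_distribution(ranks2: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the group-1 rank sum over all labelings.

    ``ranks2`` are pooled mid-ranks doubled to integers (mid-ranks are
    half-integers at worst).  Returns (support of doubled rank sums,
    counts), where counts sum to C(n, n1).
    """
    total = int(ranks2.sum())
    # dp[k, s] = number of size-k subsets of the ranks seen so far with
    # doubled rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] = dp[1:, r:] + dp[:-1, : total + 1 - r]
    support = np.arange(total + 1)
    counts = dp[n1]
    keep = counts > 0
    return support[keep], counts[keep]


def mann_whitney_exact(a, b, method: str = "auto") -> TestResult:
    """Mann-Whitney U test of two independent samples.

    U is computed from mid-ranks (U of sample ``a``).  With
    ``method='auto'`` the p-value is exact for pooled samples up to
    ``EXACT_MW_LIMIT`` and a tie-corrected normal approximation beyond;
    ``'exact'``/``'asymptotic'`` force either path.  The z statistic
    (continuity-corrected, tie-corrected) is always reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    # tie-corrected normal approximation (always reported as z)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var > 0:
        cc = 0.5 * np.sign(u1 - mu)
        z = (u1 - mu - cc) / math.sqrt(var)
    else:
        z = 0.0

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_MW_LIMIT)
    if method not in ("auto", "exact", "asymptotic"):
        raise StatsError(f"unknown method {method!r}")
    if use_exact:
        ranks2 = np.rint(ranks * 2).astype(int)
        support, counts = _ranksum_distribution(ranks2, n1)
        total = counts.sum()
        obs = int(round(r1 * 2))
        p_le = counts[support <= obs].sum() / total
        p_ge = counts[support >= obs].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult("mann-whitney", u1, float(p), n1, n2, exact=True, z=float(z))
    if var <= 0:
        p = 1.0
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("mann-whitney", u1, float(min(1.0, p)), n1, n2, exact=False, z=float(z))


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x, y, method: str = "auto") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of the mid-ranks (tie-corrected).  The
    p-value uses the t approximation with n-2 degrees of freedom; with
    ``method='exact'`` (n <= 10) the full permutation distribution of rho
    is enumerated instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise StatsError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rho undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)

    if method == "exact":
        if n > 10:
            raise StatsError("exact permutation p only supported for n <= 10")
        # vectorized enumeration: rho is affine in sum(rx * perm(ry)), so
        # compare cross-products over all n! permutations at once
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        ryc_sq = float(((ry - ry.mean()) ** 2).sum())
        denom = math.sqrt(float((rxc**2).sum()) * ryc_sq)
        rhos = (perms - ry.mean()) @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return TestResult("spearman", rho, p, n, n, exact=True)
    if method not in ("auto", "t", "exact"):
        raise StatsError(f"unknown method {method!r}")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult("spearman", rho, float(min(1.0, p)), n, n, exact=False)
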