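"""Multiscale sample entropy and the Complexity Index.

The central statistic of the package.  A tachogram (interbeat-interval
series, ms) is coarse-grained over scale factors tau = 1..max_scale by
averaging non-overlapping windows of length tau.  Sample entropy

    SE(m, r, N) = -ln( phi^{m+1}(r) / phi^m(r) )

is computed on each coarse-grained series, where phi^m(r) is the
probability that two distinct length-m templates lie within a Chebyshev
distance r of each other (self-matches excluded, Richman–Moorman
convention).  The Complexity Index is the sum of SE over a scale range:
CI_s over scales 1-5 (high-frequency, vagally dominated regime) and
CI_l over scales 6-10 (low-frequency, sympathetically dominated regime).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

__all__ = [
    "EntropyParams",
    "CoarseGrainedSeries",
    "TemplateMatchStats",
    "MSECurve",
    "ComplexityIndices",
    "EntropyError",
    "UndefinedScaleError",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "complexity_index",
    "complexity_indices",
    "classify_by_threshold",
    "UWS_LABEL",
    "MCS_LABEL",
    "DEFAULT_CI_L_THRESHOLD",
]

UWS_LABEL = "UWS"
MCS_LABEL = "MCS"

#: Decision boundary on CI_l reported for the reference cohort
#: (CI_l < threshold -> UWS, CI_l >= threshold -> MCS).
DEFAULT_CI_L_THRESHOLD = 4.876


class EntropyError(ValueError):
    """Invalid input to an entropy computation."""


class UndefinedScaleError(EntropyError):
    """A scale required for a complexity index carries no defined entropy."""


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the multiscale sample entropy computation.

    Attributes
    ----------
    m : int
        Template (embedding) length: number of consecutive points per
        pattern.  Default 2.
    r : float
        Match tolerance as a fraction of the reference standard
        deviation.  Default 0.15.
    max_scale : int
        Largest coarse-graining factor tau.  Default 10.
    r_convention : str
        ``"fixed_scale1_sd"`` (default): the absolute tolerance r*SD is
        computed once from the original (scale-1) series and held fixed
        across scales — the standard multiscale-entropy convention.
        ``"per_scale_sd"``: the tolerance is recomputed from each
        coarse-grained series.
    """

    m: int = 2
    r: float = 0.15
    max_scale: int = 10
    r_convention: str = "fixed_scale1_sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise EntropyError(f"m must be >= 1, got {self.m}")
        if not 0.0 < self.r < 1.0:
            raise EntropyError(f"r must lie in (0, 1), got {self.r}")
        if self.max_scale < 1:
            raise EntropyError(f"max_scale must be >= 1, got {self.max_scale}")
        if self.r_convention not in ("fixed_scale1_sd", "per_scale_sd"):
            raise EntropyError(f"unknown r_convention {self.r_convention!r}")


@dataclass(frozen=True)
class CoarseGrainedSeries:
    """A series averaged over non-overlapping windows of length ``scale``."""

    scale: int
    values: np.ndarray


@dataclass(frozen=True)
class TemplateMatchStats:
    """Match-pair bookkeeping behind one sample-entropy value.

    ``b_count``/``a_count`` are unordered template-pair counts of length
    m and m+1 respectively, over the same N-m template start positions,
    excluding self-matches.  ``phi_m``/``phi_m1`` are the corresponding
    match probabilities.
    """

    b_count: int
    a_count: int
    phi_m: float
    phi_m1: float
    tolerance_abs: float

    def __post_init__(self) -> None:
        if self.a_count > self.b_count:
            raise EntropyError("a_count cannot exceed b_count")


@dataclass(frozen=True)
class MSECurve:
    """Sample entropy per coarse-graining scale, with validity flags."""

    scales: np.ndarray
    se: np.ndarray
    defined: np.ndarray
    params: EntropyParams
    sd_ref: float
    stats: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if not np.array_equal(self.scales, np.arange(1, len(self.scales) + 1)):
            raise EntropyError("scales must be contiguous from 1")
        finite = np.isfinite(self.se)
        if not np.array_equal(finite, self.defined):
            raise EntropyError("se must be finite exactly where defined")


@dataclass(frozen=True)
class ComplexityIndices:
    """CI over short (1-5) and long (6-10) scale ranges, plus the total."""

    ci_s: float
    ci_l: float
    ci_total: float


def coarse_grain(series, tau: int) -> CoarseGrainedSeries:
    """Average ``series`` over non-overlapping windows of length ``tau``.

    The output has length floor(N / tau); a trailing incomplete window is
    dropped.  ``tau = 1`` returns the original series.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise EntropyError("series must be one-dimensional")
    if tau < 1:
        raise EntropyError(f"tau must be >= 1, got {tau}")
    n = x.size // tau
    if n < 1:
        raise EntropyError(f"series of length {x.size} is shorter than tau={tau}")
    y = x[: n * tau].reshape(n, tau).mean(axis=1)
    return CoarseGrainedSeries(scale=tau, values=y)


def _count_pairs_within(emb: np.ndarray, tol: float) -> int:
    """Unordered pairs of rows of ``emb`` within Chebyshev distance <= tol."""
    tree = cKDTree(emb)
    ordered = tree.count_neighbors(tree, tol, p=np.inf)
    return int(ordered - emb.shape[0]) // 2


def sample_entropy(series, m: int, tolerance_abs: float):
    """Sample entropy of a series at template length ``m``.

    Matches are counted with the Chebyshev (max-coordinate) distance over
    the N-m templates that admit both a length-m and a length-(m+1)
    pattern, excluding self-matches.  Returns ``(se, TemplateMatchStats)``;
    ``se`` is NaN (never a silent infinity) when either count is zero, in
    which case the stats record why.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise EntropyError("series must be one-dimensional")
    if x.size <= m + 1:
        raise EntropyError(
            f"series length {x.size} too short for m={m} (need > m+1 points)"
        )
    if not tolerance_abs > 0:
        raise EntropyError(f"tolerance_abs must be > 0, got {tolerance_abs}")

    n_templates = x.size - m  # same template count for both lengths
    emb_m = sliding_window_view(x, m)[:n_templates]
    emb_m1 = sliding_window_view(x, m + 1)

    b = _count_pairs_within(np.ascontiguousarray(emb_m), tolerance_abs)
    a = _count_pairs_within(np.ascontiguousarray(emb_m1), tolerance_abs)

    n_pairs = n_templates * (n_templates - 1) // 2
    stats = TemplateMatchStats(
        b_count=b,
        a_count=a,
        phi_m=b / n_pairs,
        phi_m1=a / n_pairs,
        tolerance_abs=float(tolerance_abs),
    )
    if a == 0 or b == 0:
        return float("nan"), stats
    return -math.log(a / b), stats


def mse_curve(ibi, params: EntropyParams | None = None) -> MSECurve:
    """Multiscale entropy curve SE(tau) for tau = 1..max_scale.

    Each scale is coarse-grained and fed to :func:`sample_entropy` with an
    absolute tolerance of ``r * SD_ref``.  Under the default convention
    SD_ref is the sample standard deviation of the scale-1 series, held
    fixed across scales; under ``per_scale_sd`` the tolerance tracks each
    coarse series' own SD.  Scales whose coarse series is too short or
    yields zero matches are flagged undefined rather than erroring.
    """
    params = params or EntropyParams()
    x = np.asarray(getattr(ibi, "intervals", ibi), dtype=float)
    if x.size == 0:
        raise EntropyError("empty series")
    sd_ref = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd_ref <= 0:
        # constant series: every template matches, SE = 0 at every scale
        # long enough to host a template; honour that limit explicitly.
        sd_ref = 0.0

    scales = np.arange(1, params.max_scale + 1)
    se = np.full(params.max_scale, np.nan)
    defined = np.zeros(params.max_scale, dtype=bool)
    stats_list = []
    if x.size // params.max_scale <= params.m + 1:
        warnings.warn(
            f"series of length {x.size} is too short for every scale up to "
            f"{params.max_scale}; short scales will be flagged undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    for i, tau in enumerate(scales):
        if x.size // tau <= params.m + 1:
            stats_list.append(None)
            continue
        cg = coarse_grain(x, int(tau))
        if params.r_convention == "per_scale_sd":
            sd = float(np.std(cg.values, ddof=1))
        else:
            sd = sd_ref
        if sd <= 0:
            # zero-variance series at this scale: all templates match.
            se[i] = 0.0
            defined[i] = True
            stats_list.append(None)
            continue
        val, st = sample_entropy(cg.values, params.m, params.r * sd)
        stats_list.append(st)
        if math.isfinite(val):
            se[i] = val
            defined[i] = True
    return MSECurve(
        scales=scales,
        se=se,
        defined=defined,
        params=params,
        sd_ref=sd_ref,
        stats=tuple(stats_list),
    )


def complexity_index(curve: MSECurve, scale_range=(1, 5), strict: bool = True) -> float:
    """Sum of SE(tau) over an inclusive scale range.

    In strict mode (default) an undefined scale inside the range raises
    :class:`UndefinedScaleError` naming the scale; with ``strict=False``
    the partial sum over defined scales is returned as NaN-safe but the
    result is NaN if no scale in range is defined.
    """
    lo, hi = int(scale_range[0]), int(scale_range[1])
    if lo < 1 or hi > curve.scales[-1] or lo > hi:
        raise EntropyError(f"scale range [{lo}, {hi}] outside curve 1..{curve.scales[-1]}")
    sel = slice(lo - 1, hi)
    if strict:
        missing = curve.scales[sel][~curve.defined[sel]]
        if missing.size:
            raise UndefinedScaleError(
                f"scale {missing[0]} is undefined inside requested range [{lo}, {hi}]"
            )
        return float(curve.se[sel].sum())
    vals = curve.se[sel][curve.defined[sel]]
    return float(vals.sum()) if vals.size else float("nan")


def complexity_indices(curve: MSECurve, strict: bool = True) -> ComplexityIndices:
    """Convenience pair: CI_s over scales 1-5 and CI_l over 6-10."""
    hi = int(curve.scales[-1])
    ci_s = complexity_index(curve, (1, min(5, hi)), strict=strict)
    ci_l = complexity_index(curve, (6, hi), strict=strict) if hi >= 6 else float("nan")
    total = ci_s + ci_l if hi >= 6 else ci_s
    return ComplexityIndices(ci_s=ci_s, ci_l=ci_l, ci_total=total)


def classify_by_threshold(ci_l: float, threshold: float = DEFAULT_CI_L_THRESHOLD) -> str:
    """Diagnose from CI_l: below the threshold UWS, at or above it MCS."""
    if not math.isfinite(ci_l):
        raise EntropyError(f"ci_l must be finite, got {ci_l}")
    return UWS_LABEL if ci_l < threshold else MCS_LABEL
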