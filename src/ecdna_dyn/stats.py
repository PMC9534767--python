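"""Distribution comparison and sampling-resolution statistics.

Copy-number data are integer-valued, so empirical CDFs have heavy ties.
The two-sample Kolmogorov-Smirnov statistic is still well defined (sup of
the ECDF difference); the asymptotic p-value is conservative under ties,
which matches how such comparisons are conventionally reported.  An optional
permutation p-value is available for tie-heavy samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.stats

from ecdna_dyn.errors import NotEstimableError, ParameterError

__all__ = [
    "KSResult",
    "SubsampleReport",
    "ks_two_sample",
    "shapiro_wilk",
    "subsample_convergence",
]


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison result."""

    D: float
    p: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.D <= 1.0 and 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class SubsampleReport:
    """KS distance and rejection rates of subsamples vs. the full distribution.

    ``mean_D[i]`` is the average KS statistic of ``n_resamples`` random
    subsets of size ``sizes[i]`` against the full sample; ``rejection_rate``
    is the fraction of those subsets whose asymptotic KS p-value falls below
    ``alpha``.
    """

    sizes: tuple[int, ...]
    mean_D: tuple[float, ...]
    rejection_rate: tuple[float, ...]
    n_resamples: int
    alpha: float


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymp",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> KSResult:
    """Two-sample KS statistic ``D = sup |ECDF_x - ECDF_y|`` and p-value.

    ``method="asymp"`` uses the Kolmogorov limiting distribution at the
    effective size ``n_x n_y / (n_x + n_y)``; ``method="permutation"``
    recomputes ``D`` over ``n_permutations`` random relabelings, which is
    exact in expectation for discrete, tie-heavy data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    if method == "asymp":
        res = scipy.stats.ks_2samp(x, y, method="asymp")
        return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)), x.size, y.size)
    if method == "permutation":
        d_obs = float(scipy.stats.ks_2samp(x, y, method="asymp").statistic)
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        n = x.size
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            d = scipy.stats.ks_2samp(pooled[:n], pooled[n:], method="asymp").statistic
            if d >= d_obs - 1e-15:
                hits += 1
        return KSResult(d_obs, (hits + 1) / (n_permutations + 1), x.size, y.size)
    raise ParameterError(f"unknown KS method {method!r}")


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000 observations.

    Uses the Royston order-statistic-weight approximation.  A constant
    sample has undefined W.
    """
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ParameterError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise NotEstimableError("Shapiro-Wilk W is undefined for a constant sample")
    res = scipy.stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _int_cdf(values: np.ndarray, k_max: int) -> np.ndarray:
    """ECDF of a non-negative integer sample on the grid 0..k_max."""
    counts = np.bincount(values, minlength=k_max + 1)
    return np.cumsum(counts) / values.size


def _ks_finite_p(d: float, n_x: int, n_y: int) -> float:
    """Finite-sample KS p-value at the effective size ``n_x n_y/(n_x+n_y)``.

    When one sample is much larger than the other the comparison is
    effectively one-sample against a known distribution, for which the
    finite-n Kolmogorov distribution is the correct calibration (the
    asymptotic form is noticeably biased below n ~ 100).
    """
    en = int(round(n_x * n_y / (n_x + n_y)))
    return float(min(1.0, scipy.stats.kstwo.sf(d, max(en, 1))))


def subsample_convergence(
    source: Union[Sequence[int], np.ndarray],
    sizes: Sequence[int] = (25, 50, 100, 500),
    n_resamples: int = 500,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> SubsampleReport:
    """In-silico resolution trial: how well do small samples of cells recover
    the true copy-number distribution?

    For each requested sample size, ``n_resamples`` subsets are drawn without
    replacement from the full per-cell copy-number sample and compared to it
    with the KS statistic.  The mean KS distance shrinks as the sample grows;
    the rejection rate at level ``alpha`` quantifies how often a sample of
    that size would be (wrongly) declared different from its own source.

    ``source`` must be a raw per-cell integer copy-number sample much larger
    than the largest requested size.  The ECDFs are evaluated on the integer
    support, which is exact for count data and fast for very large sources.
    """
    source = np.asarray(source)
    if source.ndim != 1 or source.size == 0:
        raise ParameterError("source must be a non-empty 1-D sample of counts")
    if np.any(source < 0):
        raise ParameterError("copy counts must be non-negative")
    sizes = tuple(int(s) for s in sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ParameterError("sizes must be strictly increasing")
    if sizes[-1] >= source.size:
        raise ParameterError("largest size must be smaller than the source sample")

    rng = np.random.default_rng(seed)
    k_max = int(source.max())
    full_cdf = _int_cdf(source.astype(np.int64), k_max)
    n_src = source.size

    mean_d, reject = [], []
    for size in sizes:
        d_vals = np.empty(n_resamples)
        p_vals = np.empty(n_resamples)
        for r in range(n_resamples):
            sub = rng.choice(source, size=size, replace=False)
            d = float(np.max(np.abs(_int_cdf(sub.astype(np.int64), k_max) - full_cdf)))
            d_vals[r] = d
            p_vals[r] = _ks_finite_p(d, size, n_src)
        mean_d.append(float(d_vals.mean()))
        reject.append(float(np.mean(p_vals < alpha)))
    return SubsampleReport(sizes, tuple(mean_d), tuple(reject), n_resamples, alpha)
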