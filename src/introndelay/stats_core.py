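"""Shared statistical machinery.

Bootstrap-normal confidence intervals, a permuted Kruskal-Wallis rank-sum
test, 2x2 chi-square, simple OLS, and a Bonferroni helper. All stochastic
procedures take an explicit seed and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .models import ConfigurationError, InputError


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    n_resamples: int
    seed: Optional[int]


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: Optional[int]


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    stderr: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    df: int
    table: np.ndarray
    expected: np.ndarray


def bootstrap_ci_normal(
    values: Sequence[float],
    stat: Callable[[np.ndarray], float] = np.median,
    n: int = 10_000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> BootstrapCI:
    """Normal-approximation bootstrap CI: stat +/- z * sd(resampled stats)."""
    if n < 1:
        raise ConfigurationError("n_resamples must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n, values.size))
    resampled = values[idx]
    if stat is np.median:
        boot = np.median(resampled, axis=1)
    elif stat is np.mean:
        boot = resampled.mean(axis=1)
    else:
        boot = np.apply_along_axis(stat, 1, resampled)
    point = float(stat(values))
    se = float(boot.std(ddof=1))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return BootstrapCI(point, point - z * se, point + z * se, se, n, seed)


def _kw_h(ranks: np.ndarray, starts: np.ndarray, sizes: np.ndarray, tie_c: float) -> float:
    n_total = ranks.shape[-1]
    sums = np.add.reduceat(ranks, starts, axis=-1)
    means = sums / sizes
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(
        sizes * (means - (n_total + 1) / 2.0) ** 2, axis=-1
    )
    return h / tie_c


def kruskal_wallis_h(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis H with mid-rank tie correction."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    if tie_c == 0.0:
        return 0.0  # all values identical
    sizes = np.array([a.size for a in arrays])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return float(_kw_h(ranks, starts, sizes, tie_c))


def permutation_kruskal_wallis(
    groups: Sequence[Sequence[float]],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    batch: int = 2000,
) -> PermutationTestResult:
    """Kruskal-Wallis rank-sum test with a label-permutation null.

    p = (1 + #{H_perm >= H_obs}) / (n_perm + 1), so p is never exactly 0.
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InputError("every group must contain at least 2 values")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_c == 0.0:
        return PermutationTestResult(0.0, 1.0, n_perm, seed)
    sizes = np.array([a.size for a in arrays])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    observed = float(_kw_h(ranks, starts, sizes, tie_c))
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # permute ranks by sorting random keys row-wise
        perm = rng.random((b, n)).argsort(axis=1)
        h = _kw_h(ranks[perm], starts, sizes, tie_c)
        exceed += int(np.sum(h >= observed - 1e-12))
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationTestResult(observed, p, n_perm, seed)


def chi_square_2x2(table, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table (1 df), optional Yates correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise InputError("table must be 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row <= 0) or np.any(col <= 0):
        raise InputError("chi-square undefined: a margin of the table is zero")
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(sps.chi2.sf(stat, 1))
    return ChiSquareResult(stat, p, 1, obs, expected)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> OLSFit:
    """Ordinary least squares of y on x with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need >= 3 paired points")
    if np.allclose(x, x[0]):
        raise InputError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # y constant -> rvalue nan
        r2 = 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return OLSFit(float(res.slope), float(res.intercept), r2, p, float(res.stderr))


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)
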