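"""Length-class trajectory analysis of the maternal-to-zygotic transition.

Genes are split into short (<5 kb) and long (>=5 kb) classes on primary
transcript length (or total orthologous intron length for cross-species
work). Per (origin x length class) cell we summarize median expression per
timepoint with bootstrap-normal CIs, regress the medians on timepoint index,
and test whether the long/short gap changes over development (ANCOVA
interaction). Categorical enrichments (intronless x origin; stability x
length class) use 2x2 chi-square tests.

Expression is analyzed on the log2(x+1) scale by default; pass
``log_transform=False`` for raw units (e.g. already-log microarray values).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats_core
from .models import GeneModel, InputError, LENGTH_THRESHOLD

logger = logging.getLogger(__name__)

SHORT, LONG = "short", "long"


def assign_length_class(
    basis_values: pd.Series,
    threshold: int = LENGTH_THRESHOLD,
    basis: str = "primary_length",
) -> pd.DataFrame:
    """Partition genes into short (< threshold) and long (>= threshold).

    ``basis_values`` maps gene_id -> length in bp (primary transcript length
    or total orthologous intron length). Genes with missing values are
    excluded with a warning.
    """
    values = pd.Series(basis_values, dtype=float)
    missing = values.index[values.isna()]
    if len(missing):
        logger.warning(
            "%d genes lack a %s value and were excluded from length classes",
            len(missing),
            basis,
        )
        values = values.dropna()
    cls = np.where(values >= threshold, LONG, SHORT)
    return pd.DataFrame(
        {
            "gene_id": values.index,
            "basis": basis,
            "length_class": cls,
            "basis_value": values.values,
            "threshold": threshold,
        }
    ).set_index("gene_id")


@dataclass
class ThresholdReport:
    threshold: Optional[int]
    increment: int
    bin_edges: List[int]
    bin_sizes: Dict[int, int]
    pairwise: pd.DataFrame  # bin_a, bin_b, timepoint, p_raw, p_bonferroni, significant


def select_length_threshold(
    matrix: pd.DataFrame,
    lengths: pd.Series,
    increment: int = 5000,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: Optional[int] = 0,
    min_bin_size: int = 5,
) -> ThresholdReport:
    """Choose the short/long boundary by binning genes into ``increment``-bp
    length bins and comparing per-timepoint expression distributions between
    all bin pairs (permuted Kruskal-Wallis, Bonferroni over pairs x
    timepoints). The chosen threshold is the smallest bin edge such that all
    bins at or above it are mutually indistinguishable while each differs
    from every bin below it. Returns threshold None when no edge qualifies.
    """
    lengths = lengths.reindex(matrix.index).dropna()
    mat = matrix.loc[lengths.index]
    bin_of = (lengths // increment).astype(int)
    sizes = bin_of.value_counts()
    bins = sorted(sizes.index[sizes >= min_bin_size])
    if len(bins) < 2:
        raise InputError(
            "all genes fall in a single populated length bin; threshold undefined"
        )
    pairs = list(itertools.combinations(bins, 2))
    m_tests = len(pairs) * mat.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        ga = mat.loc[bin_of.index[bin_of == a]]
        gb = mat.loc[bin_of.index[bin_of == b]]
        for tp in mat.columns:
            res = stats_core.permutation_kruskal_wallis(
                [ga[tp].values, gb[tp].values],
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            p_corr = min(1.0, res.p_value * m_tests)
            rows.append(
                {
                    "bin_a": a,
                    "bin_b": b,
                    "timepoint": tp,
                    "p_raw": res.p_value,
                    "p_bonferroni": p_corr,
                    "significant": p_corr < alpha,
                }
            )
    pairwise = pd.DataFrame(rows)
    sig = {
        (r.bin_a, r.bin_b): False for r in pairwise.itertuples()
    }
    for r in pairwise.itertuples():
        if r.significant:
            sig[(r.bin_a, r.bin_b)] = True

    chosen = None
    for edge_bin in bins[1:]:
        above = [b for b in bins if b >= edge_bin]
        below = [b for b in bins if b < edge_bin]
        ok_above = all(not sig[(a, b)] for a, b in itertools.combinations(above, 2))
        ok_split = all(sig[(min(a, b), max(a, b))] for a in below for b in above)
        if ok_above and ok_split:
            chosen = edge_bin * increment
            break
    return ThresholdReport(
        threshold=chosen,
        increment=increment,
        bin_edges=[b * increment for b in bins],
        bin_sizes={b * increment: int(sizes[b]) for b in bins},
        pairwise=pairwise,
    )


@dataclass
class TrajectorySummary:
    """Per-cell median trajectories with bootstrap CIs and per-cell OLS fits."""

    medians: pd.DataFrame  # origin, length_class, timepoint, median, ci_low, ci_high, n
    fits: Dict[Tuple[str, str], stats_core.OLSFit] = field(default_factory=dict)
    log_transform: bool = True


def median_trajectory(
    matrix: pd.DataFrame,
    classes: pd.DataFrame,
    n_boot: int = 10_000,
    seed: Optional[int] = 0,
    log_transform: bool = True,
    min_genes: int = 3,
) -> TrajectorySummary:
    """Median expression per (origin, length class, timepoint) with 95%
    bootstrap-normal CIs, plus an OLS fit of median on timepoint index per
    cell. ``classes`` must carry ``origin`` and ``length_class`` columns
    indexed by gene_id."""
    for col in ("origin", "length_class"):
        if col not in classes.columns:
            raise InputError(f"classes table lacks column {col!r}")
    common = matrix.index.intersection(classes.index)
    mat = matrix.loc[common]
    if log_transform:
        mat = np.log2(mat + 1.0)
    cls = classes.loc[common]
    rng = np.random.default_rng(seed)
    rows = []
    fits: Dict[Tuple[str, str], stats_core.OLSFit] = {}
    for (origin, lclass), sub_ids in cls.groupby(["origin", "length_class"]).groups.items():
        sub = mat.loc[list(sub_ids)]
        if len(sub) < min_genes:
            raise InputError(
                f"cell (origin={origin}, length_class={lclass}) has only "
                f"{len(sub)} genes (< {min_genes})"
            )
        med_by_t = []
        for ti, tp in enumerate(mat.columns):
            vals = sub[tp].values
            ci = stats_core.bootstrap_ci_normal(
                vals, stat=np.median, n=n_boot, seed=int(rng.integers(2**31))
            )
            med_by_t.append(ci.estimate)
            rows.append(
                {
                    "origin": origin,
                    "length_class": lclass,
                    "timepoint": tp,
                    "t_index": ti,
                    "median": ci.estimate,
                    "ci_low": ci.ci_low,
                    "ci_high": ci.ci_high,
                    "n_genes": len(sub),
                }
            )
        fits[(origin, lclass)] = stats_core.ols_fit(
            np.arange(len(mat.columns)), np.array(med_by_t)
        )
    return TrajectorySummary(
        medians=pd.DataFrame(rows), fits=fits, log_transform=log_transform
    )


@dataclass
class AncovaResult:
    f_interaction: float
    p_interaction: float
    interaction_slope: float
    df_num: int
    df_den: int
    leave_one_out: List[Tuple[int, float, float]]  # (dropped index, F, p)


def ancova_interaction(
    medians_a: Sequence[float],
    medians_b: Sequence[float],
    robustness: bool = True,
) -> AncovaResult:
    """Test whether the gap between two classes' median trajectories changes
    over time: fit median ~ C(time) + class + time:class on the per-timepoint
    medians and F-test the linear time-by-class interaction. Modelling the
    shared time course as a factor (rather than a line) cancels any common
    trajectory shape exactly, so the interaction test stays calibrated even
    when activation dynamics are strongly nonlinear; it is equivalent to
    regressing the per-timepoint class difference on timepoint index. With
    ``robustness``, re-fit with each timepoint left out in turn."""
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.size != b.size:
        raise InputError("both classes must be observed at the same timepoints")
    if a.size < 4:
        raise InputError("ANCOVA needs >= 4 timepoints")

    def fit(aa: np.ndarray, bb: np.ndarray):
        # with time as a factor, the interaction inference reduces exactly to
        # OLS of the per-timepoint difference on timepoint index (df = T - 2)
        from scipy import stats as sps

        T = aa.size
        t = np.arange(T, dtype=float)
        d = bb - aa
        slope, intercept = np.polyfit(t, d, 1)
        resid = d - (intercept + slope * t)
        df_den = T - 2
        rss = float(resid @ resid)
        sxx = float(((t - t.mean()) ** 2).sum())
        scale = max(np.max(np.abs(d)), np.max(np.abs(aa)), np.max(np.abs(bb)), 1.0)
        if rss <= (1e-10 * scale) ** 2 * T:  # numerically perfect fit
            if abs(slope) <= 1e-10 * scale:
                return 0.0, 1.0, float(slope), df_den
            return np.inf, 0.0, float(slope), df_den
        se = np.sqrt(rss / df_den / sxx)
        f = float((slope / se) ** 2)
        p = float(2.0 * sps.t.sf(abs(slope / se), df_den))
        return f, p, float(slope), df_den

    f, p, slope, df_den = fit(a, b)
    loo: List[Tuple[int, float, float]] = []
    if robustness:
        for i in range(a.size):
            if a.size - 1 < 4:
                break
            keep = np.arange(a.size) != i
            fi, pi, _, _ = fit(a[keep], b[keep])
            loo.append((i, fi, pi))
    return AncovaResult(f, p, slope, 1, df_den, loo)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    proportions: pd.DataFrame
    chi2: stats_core.ChiSquareResult


def _two_by_two(labels_rows: pd.Series, labels_cols: pd.Series, yates: bool) -> EnrichmentResult:
    common = labels_rows.index.intersection(labels_cols.index)
    if len(common) == 0:
        raise InputError("no genes shared between the two label tables")
    tab = pd.crosstab(labels_rows.loc[common], labels_cols.loc[common])
    if tab.shape != (2, 2):
        raise InputError(
            f"expected a 2x2 table, got {tab.shape}; a margin is empty"
        )
    res = stats_core.chi_square_2x2(tab.values, yates=yates)
    props = tab.div(tab.sum(axis=1), axis=0)
    return EnrichmentResult(tab, props, res)


def intronless_enrichment(
    genes: Sequence[GeneModel],
    origins: pd.Series,
    yates: bool = False,
) -> EnrichmentResult:
    """Chi-square test of (origin x intronless) among the supplied genes —
    is the intronless state overrepresented among zygotic genes?"""
    intronless = pd.Series(
        {g.gene_id: "intronless" if g.is_intronless else "has_introns" for g in genes}
    )
    return _two_by_two(pd.Series(origins), intronless, yates)


def degradation_class_test(
    length_classes: pd.Series,
    stability: pd.Series,
    yates: bool = False,
) -> EnrichmentResult:
    """Chi-square test of (length class x stable/degraded) — do long genes
    differ from short genes in transcript stability?"""
    return _two_by_two(pd.Series(length_classes), pd.Series(stability), yates)
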