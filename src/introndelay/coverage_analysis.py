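"""5'->3' coverage-bias analysis: the discriminator between intron delay and
initiation control.

If long zygotic genes are rate-limited by transcription time, early samples
should contain truncated nascent transcripts and read coverage should decay
from the 5' end of the transcript, flattening as cell cycles lengthen; under
pure initiation control coverage stays uniform. We measure this with ten
non-overlapping 500-bp transcript-oriented windows over the first 5 kb of
each gene (exonic bases only), scale each gene's windows to its maximal
window, aggregate per-window medians across genes, and regress the median on
window number. A complementary statistic is the per-gene ratio of RPKM in
the 5'-most versus 3'-most 1 kb of exonic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats_core
from .models import GeneModel, InputError

N_WINDOWS_DEFAULT = 10


@dataclass
class CoverageProfile:
    """Windowed fractional coverage of one gene.

    ``fractional[i]`` is window i's reads-per-exonic-base coverage scaled to
    the gene's maximal window; ``ignored[i]`` marks windows with no exonic
    sequence (or beyond the gene end). ``has_coverage`` is False when no read
    touched any window, in which case ``fractional`` is all zero.
    """

    gene_id: str
    window: int
    span: int
    mean_coverage: np.ndarray
    fractional: np.ndarray
    exonic_bp: np.ndarray
    ignored: np.ndarray
    has_coverage: bool


def _transcript_starts(reads: pd.DataFrame, gene: GeneModel) -> np.ndarray:
    """5'-most transcript-coordinate offset of each read, in transcription
    orientation."""
    if len(reads) == 0:
        return np.empty(0, dtype=int)
    rs = reads["start"].to_numpy()
    re = reads["end"].to_numpy()
    if gene.strand == "+":
        return rs - gene.start
    return gene.end - re


def windowed_coverage(
    reads: pd.DataFrame,
    gene: GeneModel,
    window: int = 500,
    span: int = 5000,
) -> CoverageProfile:
    """Fractional exonic coverage in non-overlapping windows over the first
    ``span`` bp of the transcript (5'->3'): reads are counted into the window
    holding their 5'-most transcript position, each window is normalized by
    its exonic length, and all windows are scaled to the maximal window."""
    n_win = span // window
    s = min(span, gene.primary_length)
    starts = _transcript_starts(reads, gene)
    starts = starts[(starts >= 0) & (starts < s)]
    per_window = np.bincount(starts // window, minlength=n_win)[:n_win]

    exon_mask = np.zeros(s, dtype=bool)
    for ts, te in gene.exon_segments_transcript():
        ts, te = int(ts), min(int(te), s)
        if te > ts:
            exon_mask[ts:te] = True

    exonic_bp = np.zeros(n_win, dtype=int)
    mean_cov = np.zeros(n_win)
    ignored = np.zeros(n_win, dtype=bool)
    for i in range(n_win):
        a, b = i * window, min((i + 1) * window, s)
        if b <= a:
            ignored[i] = True
            continue
        exonic_bp[i] = int(exon_mask[a:b].sum())
        if exonic_bp[i] == 0:
            ignored[i] = True
            continue
        mean_cov[i] = per_window[i] / exonic_bp[i]
    mx = mean_cov[~ignored].max() if (~ignored).any() else 0.0
    has_cov = mx > 0
    fractional = mean_cov / mx if has_cov else np.zeros(n_win)
    return CoverageProfile(
        gene_id=gene.gene_id,
        window=window,
        span=span,
        mean_coverage=mean_cov,
        fractional=fractional,
        exonic_bp=exonic_bp,
        ignored=ignored,
        has_coverage=has_cov,
    )


def _profile_matrix(profiles: Sequence[CoverageProfile]) -> np.ndarray:
    """Stack fractional profiles as a genes x windows matrix with NaN at
    ignored windows; genes without coverage are dropped."""
    rows = [
        np.where(p.ignored, np.nan, p.fractional)
        for p in profiles
        if p.has_coverage
    ]
    if not rows:
        return np.empty((0, 0))
    return np.vstack(rows)


@dataclass
class MedianProfile:
    medians: np.ndarray  # per-window median fractional coverage (NaN if no data)
    window_numbers: np.ndarray  # 1-based indices of valid windows
    fit: stats_core.OLSFit
    n_genes: int


def aggregate_median_profile(
    profiles: Sequence[CoverageProfile],
    min_genes: int = 5,
) -> MedianProfile:
    """Per-window median fractional coverage across genes (ignored windows
    excluded) and the OLS slope of median versus window number (1..n)."""
    mat = _profile_matrix(profiles)
    if mat.shape[0] < min_genes:
        raise InputError(
            f"only {mat.shape[0]} genes with coverage (< {min_genes} required)"
        )
    with np.errstate(all="ignore"):
        med = np.nanmedian(mat, axis=0)
    valid = ~np.isnan(med)
    if valid.sum() < 2:
        raise InputError("fewer than 2 windows with data; slope undefined")
    wn = np.arange(1, mat.shape[1] + 1)
    fit = stats_core.ols_fit(wn[valid], med[valid])
    return MedianProfile(medians=med, window_numbers=wn[valid], fit=fit, n_genes=mat.shape[0])


def bootstrap_slope_ci(
    profiles: Sequence[CoverageProfile],
    n_boot: int = 1000,
    seed: Optional[int] = 0,
    min_genes: int = 5,
) -> stats_core.BootstrapCI:
    """Normal-approximation bootstrap CI of the aggregate profile slope,
    resampling genes with replacement."""
    mat = _profile_matrix(profiles)
    if mat.shape[0] < min_genes:
        raise InputError(f"only {mat.shape[0]} genes with coverage")
    rng = np.random.default_rng(seed)
    wn = np.arange(1, mat.shape[1] + 1)

    def slope_of(m: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            med = np.nanmedian(m, axis=0)
        valid = ~np.isnan(med)
        if valid.sum() < 2:
            return np.nan
        return stats_core.ols_fit(wn[valid], med[valid]).slope

    point = slope_of(mat)
    boot = np.array(
        [
            slope_of(mat[rng.integers(0, mat.shape[0], size=mat.shape[0])])
            for _ in range(n_boot)
        ]
    )
    boot = boot[np.isfinite(boot)]
    se = float(boot.std(ddof=1))
    return stats_core.BootstrapCI(point, point - 1.96 * se, point + 1.96 * se, se, n_boot, seed)


def slope_difference_trend(
    slopes_a: pd.Series,
    slopes_b: pd.Series,
) -> stats_core.OLSFit:
    """Regress the per-timepoint slope difference (a - b) on timepoint index.
    Both series must be indexed by the same ordered timepoints."""
    a = pd.Series(slopes_a)
    b = pd.Series(slopes_b)
    if list(a.index) != list(b.index):
        raise InputError("slope series have mismatched timepoints")
    if len(a) < 4:
        raise InputError("need >= 4 timepoints for a slope-difference trend")
    diff = (a - b).to_numpy(dtype=float)
    return stats_core.ols_fit(np.arange(len(diff), dtype=float), diff)


# ---------------------------------------------------------------------------
# 5':3' RPKM ratio
# ---------------------------------------------------------------------------

def _terminal_exonic_intervals(
    gene: GeneModel, n_bases: int, five_prime: bool
) -> List[Tuple[int, int]]:
    """Genomic intervals of the 5'-most (or 3'-most) ``n_bases`` exonic bases."""
    segs = list(gene.exon_segments_transcript())
    if not five_prime:
        # walk exons from the 3' end
        total = sum(e - s for s, e in segs)
        segs = [(s, e) for s, e in segs]
    out = []
    remaining = n_bases
    iterator = segs if five_prime else list(reversed(segs))
    for ts, te in iterator:
        if remaining <= 0:
            break
        seg_len = te - ts
        take = min(seg_len, remaining)
        if five_prime:
            a, b = ts, ts + take
        else:
            a, b = te - take, te
        out.append(gene.transcript_to_genomic(int(a), int(b)))
        remaining -= take
    return out


@dataclass
class RatioReport:
    per_gene: pd.DataFrame  # gene_id, timepoint, ratio
    medians: pd.Series  # per timepoint median ratio
    trend: Optional[stats_core.OLSFit]
    n_excluded_zero_denominator: int


def five_prime_three_prime_ratio(
    reads_by_time: Dict[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    segment: int = 1000,
    min_exonic: int = 2000,
    pseudocount: float = 0.0,
) -> RatioReport:
    """Per-gene ratio of RPKM over the 5'-most versus 3'-most ``segment``
    exonic bases, per timepoint, with the OLS trend of the per-timepoint
    median ratio on timepoint index.

    ``reads_by_time`` maps ordered timepoint labels to read tables carrying a
    ``gene_id`` assignment column (see :func:`introndelay.quantify.assign_reads`).
    Genes with exonic length < ``min_exonic`` are skipped; with no pseudocount,
    gene/timepoints whose 3' segment has zero reads are excluded.
    """
    eligible = [g for g in genes if g.exonic_length >= min_exonic]
    if not eligible:
        raise InputError(f"no genes with exonic length >= {min_exonic}")
    seg5 = {g.gene_id: _terminal_exonic_intervals(g, segment, True) for g in eligible}
    seg3 = {g.gene_id: _terminal_exonic_intervals(g, segment, False) for g in eligible}

    rows = []
    n_excluded = 0
    for tp, reads in reads_by_time.items():
        if "gene_id" not in reads.columns:
            raise InputError("read tables must carry a gene_id assignment column")
        grouped = dict(tuple(reads.groupby("gene_id"))) if len(reads) else {}
        for g in eligible:
            sub = grouped.get(g.gene_id)
            if sub is None or len(sub) == 0:
                continue
            rs = sub["start"].to_numpy()
            re = sub["end"].to_numpy()

            def overlap_count(intervals) -> int:
                hit = np.zeros(rs.size, dtype=bool)
                for a, b in intervals:
                    hit |= (rs < b) & (re > a)
                return int(hit.sum())

            c5 = overlap_count(seg5[g.gene_id]) + pseudocount
            c3 = overlap_count(seg3[g.gene_id]) + pseudocount
            if c3 <= 0:
                n_excluded += 1
                continue
            rows.append({"gene_id": g.gene_id, "timepoint": tp, "ratio": c5 / c3})
    per_gene = pd.DataFrame(rows, columns=["gene_id", "timepoint", "ratio"])
    order = list(reads_by_time.keys())
    medians = (
        per_gene.groupby("timepoint")["ratio"].median().reindex(order)
        if len(per_gene)
        else pd.Series(index=order, dtype=float)
    )
    trend = None
    usable = medians.dropna()
    if len(usable) >= 3:
        idx = [order.index(t) for t in usable.index]
        trend = stats_core.ols_fit(np.array(idx, dtype=float), usable.to_numpy())
    return RatioReport(per_gene, medians, trend, n_excluded)
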