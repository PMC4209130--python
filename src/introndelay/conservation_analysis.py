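"""Cross-species conservation of orthologous intron lengths.

For each multi-exon gene with orthologs in several species we compute the
corrected coefficient of variation of total orthologous intron length,
CV* = (1 + 1/(4n)) * CV with n the number of species, which removes the
small-sample downward bias of the plain CV. Genes are grouped into
(origin x expression tier) categories from expression quartiles at the first
timepoint, and category distributions of mean intron length or CV* are
compared with pairwise permuted Kruskal-Wallis tests, Bonferroni corrected.
Because CV* is biased low when the mean intron length is under ~150 bp, a
sensitivity re-analysis excluding such genes is provided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats_core
from .models import InputError

HIGH, LOW = "high", "low"


def cv_star(lengths: Sequence[float], ddof: int = 1) -> float:
    """Corrected coefficient of variation: (1 + 1/(4n)) * sd/mean.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population form. Scale-invariant; 0 for a constant
    vector."""
    x = np.asarray(lengths, dtype=float)
    n = x.size
    if n < 2:
        raise InputError("CV* needs at least 2 observations")
    mean = x.mean()
    if mean <= 0:
        raise InputError("CV* undefined for non-positive mean length")
    cv = x.std(ddof=ddof) / mean
    return float((1.0 + 1.0 / (4.0 * n)) * cv)


def intron_summary(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene mean orthologous intron length, CV, CV* and n_species.

    Single-exon genes (all-zero rows) and genes with any missing species are
    excluded, mirroring the restriction to multi-exon genes with complete
    ortholog sets."""
    tab = table.dropna()
    tab = tab.loc[tab.mean(axis=1) > 0]
    vals = tab.to_numpy(dtype=float)
    n = vals.shape[1]
    if n < 2:
        raise InputError("need at least 2 species for CV*")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    cv = sd / mean
    return pd.DataFrame(
        {
            "mean_length": mean,
            "cv": cv,
            "cv_star": (1.0 + 1.0 / (4.0 * n)) * cv,
            "n_species": n,
        },
        index=tab.index,
    )


def classify_expression_quartiles(
    expression: pd.Series,
    origins: pd.Series,
    within_origin: bool = True,
    min_per_origin: int = 8,
) -> pd.DataFrame:
    """Assign genes to high (top quartile) / low (bottom quartile) expression
    tiers at the first timepoint; middle-quartile genes are unassigned.
    Quartile boundaries are computed within each origin class by default."""
    expr = pd.Series(expression).dropna()
    orig = pd.Series(origins).reindex(expr.index).dropna()
    expr = expr.loc[orig.index]
    rows = []
    groups = orig.groupby(orig).groups if within_origin else {"all": orig.index}
    for oname, ids in groups.items():
        vals = expr.loc[ids]
        if len(vals) < min_per_origin:
            raise InputError(
                f"origin {oname!r} has {len(vals)} genes (< {min_per_origin})"
            )
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        if q1 >= q3:
            raise InputError(
                f"degenerate quartiles for origin {oname!r} (q1={q1}, q3={q3}); "
                "expression values are too heavily tied"
            )
        for gid in ids:
            v = expr[gid]
            tier = HIGH if v >= q3 else (LOW if v <= q1 else None)
            if tier is not None:
                rows.append({"gene_id": gid, "origin": orig[gid], "tier": tier})
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class CategoryComparison:
    summaries: pd.DataFrame  # per category: n, median, mean of the metric
    pairwise: pd.DataFrame  # cat_a, cat_b, statistic, p_raw, p_bonferroni
    metric: str
    excluded_categories: Tuple[str, ...]
    n_removed_by_filter: Optional[Dict[str, int]] = None


def compare_categories(
    table: pd.DataFrame,
    categories: pd.DataFrame,
    metric: str = "cv_star",
    n_perm: int = 10_000,
    seed: Optional[int] = 0,
    min_size: int = 5,
    ddof: int = 1,
) -> CategoryComparison:
    """Pairwise permuted Kruskal-Wallis comparisons of ``metric``
    ('cv_star' or 'mean_length') between gene categories, Bonferroni
    corrected over the number of pairs.

    ``categories`` needs 'origin' and 'tier' columns (or a precomputed
    'category' column) indexed by gene_id."""
    if metric not in ("cv_star", "mean_length"):
        raise InputError(f"unknown metric {metric!r}")
    summ = intron_summary(table, ddof=ddof)
    cats = categories.copy()
    if "category" not in cats.columns:
        if not {"origin", "tier"} <= set(cats.columns):
            raise InputError("categories need 'origin'+'tier' or 'category' columns")
        cats["category"] = cats["tier"].astype(str) + "_" + cats["origin"].astype(str)
    common = summ.index.intersection(cats.index)
    data = summ.loc[common, metric]
    labels = cats.loc[common, "category"]

    sizes = labels.value_counts()
    keep = sorted(sizes.index[sizes >= min_size])
    excluded = tuple(sorted(set(sizes.index) - set(keep)))
    if len(keep) < 1:
        raise InputError("no category meets the minimum size")
    groups = {c: data[labels == c].to_numpy() for c in keep}
    summaries = pd.DataFrame(
        {
            "n": {c: g.size for c, g in groups.items()},
            "median": {c: float(np.median(g)) for c, g in groups.items()},
            "mean": {c: float(np.mean(g)) for c, g in groups.items()},
        }
    )
    pairs = list(itertools.combinations(keep, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        res = stats_core.permutation_kruskal_wallis(
            [groups[a], groups[b]], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "cat_a": a,
                "cat_b": b,
                "statistic": res.statistic,
                "p_raw": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * len(pairs)),
            }
        )
    pairwise = pd.DataFrame(
        rows, columns=["cat_a", "cat_b", "statistic", "p_raw", "p_bonferroni"]
    )
    return CategoryComparison(summaries, pairwise, metric, excluded)


def sensitivity_filter_150(
    table: pd.DataFrame,
    categories: pd.DataFrame,
    min_mean_length: float = 150.0,
    **kwargs,
) -> CategoryComparison:
    """Re-run :func:`compare_categories` after removing genes whose mean
    orthologous intron length across species is below ``min_mean_length`` bp
    (where CV* is biased toward low values). Reports removals per category."""
    summ = intron_summary(table, ddof=kwargs.get("ddof", 1))
    keep_ids = summ.index[summ["mean_length"] >= min_mean_length]
    if len(keep_ids) == 0:
        raise InputError(
            f"no genes with mean intron length >= {min_mean_length} bp; "
            "filtered analysis is empty"
        )
    cats = categories.copy()
    if "category" not in cats.columns:
        cats["category"] = cats["tier"].astype(str) + "_" + cats["origin"].astype(str)
    before = cats.loc[cats.index.intersection(summ.index), "category"].value_counts()
    filtered = table.loc[table.index.intersection(keep_ids)]
    result = compare_categories(filtered, categories, **kwargs)
    after = cats.loc[cats.index.intersection(filtered.index), "category"].value_counts()
    removed = {
        str(c): int(before.get(c, 0) - after.get(c, 0)) for c in before.index
    }
    result.n_removed_by_filter = removed
    return result
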