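"""Read counting and RPKM-scaled expression matrices.

Counting follows the gene-level "union" rule: a read is assigned to a gene
only when the union of genes whose exons overlap any of its bases contains
exactly one gene; otherwise it is tallied as ambiguous (>=2 genes) or
no_feature (0 genes). RPKM = count / (library_size/1e6 * exonic_kb).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, InputError

ASSIGNED, AMBIGUOUS, NO_FEATURE = "assigned", "ambiguous", "no_feature"


def _exon_trees(genes: Sequence[GeneModel]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, (g.gene_id, g.strand))
    return trees


def assign_reads(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    stranded: bool = False,
) -> pd.Series:
    """Per-read gene assignment under the union rule.

    Returns a Series aligned to ``reads`` holding the gene_id, or the
    sentinel strings '__ambiguous__' / '__no_feature__'.
    """
    if not genes:
        raise InputError("annotation is empty")
    trees = _exon_trees(genes)
    out = []
    strands = reads["strand"] if "strand" in reads.columns else None
    for i, (chrom, start, end) in enumerate(
        zip(reads["chrom"], reads["start"], reads["end"])
    ):
        tree = trees.get(chrom)
        hits: Set[str] = set()
        if tree is not None:
            for iv in tree.overlap(int(start), int(end)):
                gid, gstrand = iv.data
                if stranded and strands is not None and strands.iloc[i] != "*":
                    if gstrand != strands.iloc[i]:
                        continue
                hits.add(gid)
        if len(hits) == 1:
            out.append(next(iter(hits)))
        elif len(hits) == 0:
            out.append("__no_feature__")
        else:
            out.append("__ambiguous__")
    return pd.Series(out, index=reads.index, name="gene_id")


def count_union(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    stranded: bool = False,
) -> Tuple[pd.Series, Dict[str, int]]:
    """Union-rule gene-level counts plus {assigned, ambiguous, no_feature} tallies."""
    gene_ids = [g.gene_id for g in genes]
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    if len(reads) == 0:
        return counts, {ASSIGNED: 0, AMBIGUOUS: 0, NO_FEATURE: 0}
    assigned = assign_reads(reads, genes, stranded=stranded)
    vc = assigned.value_counts()
    n_amb = int(vc.get("__ambiguous__", 0))
    n_nof = int(vc.get("__no_feature__", 0))
    per_gene = vc.drop(["__ambiguous__", "__no_feature__"], errors="ignore")
    counts.loc[per_gene.index] = per_gene.astype(int)
    tallies = {
        ASSIGNED: int(len(reads) - n_amb - n_nof),
        AMBIGUOUS: n_amb,
        NO_FEATURE: n_nof,
    }
    return counts, tallies


def rpkm(
    counts: pd.Series,
    exonic_lengths: pd.Series,
    library_size: int,
) -> pd.Series:
    """Reads Per Kilobase of exon model per Million reads.

    ``library_size`` is the total number of input reads (assigned + ambiguous
    + no_feature), matching the 'per Million mapped reads' denominator.
    """
    if library_size <= 0:
        raise InputError("library_size must be > 0")
    lens = exonic_lengths.reindex(counts.index)
    if lens.isna().any() or (lens <= 0).any():
        bad = list(lens.index[lens.isna() | (lens <= 0)])[:5]
        raise InputError(f"missing or non-positive exonic length for {bad}")
    return counts / (library_size / 1e6 * lens / 1e3)


def rpkm_matrix(
    counts: pd.DataFrame,
    exonic_lengths: pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Column-wise RPKM of a genes x timepoints count matrix. If
    ``library_sizes`` is omitted, each column's total count is used."""
    cols = {}
    for c in counts.columns:
        lib = int(library_sizes[c]) if library_sizes is not None else int(counts[c].sum())
        cols[c] = rpkm(counts[c], exonic_lengths, lib)
    return pd.DataFrame(cols, index=counts.index)


def filter_expressed(matrix: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Keep genes expressed above ``threshold`` (strictly) in at least one
    timepoint. The default of RPKM > 5 has a conventional robustness
    alternative of > 2."""
    keep = (matrix > threshold).any(axis=1)
    return matrix.loc[keep]


def read_filter_min_reads(counts: pd.DataFrame, min_reads: int = 100) -> Set[str]:
    """Genes with at least ``min_reads`` mapped reads at any individual
    timepoint — the inclusion filter for the coverage analysis."""
    if len(counts) == 0:
        return set()
    keep = (counts >= min_reads).any(axis=1)
    return set(counts.index[keep])
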