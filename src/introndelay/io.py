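"""Readers and writers for the plain-text formats the pipeline exchanges:
GTF annotations, 6-column BED read tables, and TSV tables (classifications,
expression matrices, orthologous intron lengths)."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import gffutils
import pandas as pd

from .models import GeneModel, InputError

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene and exon features (0-based intervals become 1-based
    inclusive GTF coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tintrondelay\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tintrondelay\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str, origins: Optional[pd.Series] = None) -> List[GeneModel]:
    """Load gene models from a GTF; exon structure is the union of exon
    features per gene_id. ``origins`` (gene_id -> maternal|zygotic) is
    attached when given."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: Dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        rec = exons.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        rec["exons"].append((feat.start - 1, feat.end))
    genes = []
    for gid in sorted(exons):
        rec = exons[gid]
        merged = _merge_intervals(rec["exons"])
        origin = None
        if origins is not None and gid in origins.index:
            origin = origins[gid]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(merged),
                origin=origin,
            )
        )
    return genes


def _merge_intervals(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_bed(reads: pd.DataFrame, path: str) -> None:
    reads[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for missing in BED_COLUMNS[df.shape[1] :]:
        df[missing] = {"name": ".", "score": 0, "strand": "*"}[missing]
    return df


def write_classes(classes: pd.DataFrame, path: str) -> None:
    classes.to_csv(path, sep="\t", index=False)


def read_classes(path: str) -> pd.Series:
    """gene_id -> origin from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "origin"} <= set(df.columns):
        raise InputError(f"{path}: classification TSV needs gene_id and origin columns")
    return df.set_index("gene_id")["origin"]


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_lengths(path: str, column: str = "primary_length") -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or column not in df.columns:
        raise InputError(f"{path}: needs gene_id and {column} columns")
    return df.set_index("gene_id")[column]


def write_intron_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_intron_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_flat_config(path: str) -> Dict[str, str]:
    """Flat key=value (or key: value) text config; '#' starts a comment."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                k, v = line.split("=", 1)
            elif ":" in line:
                k, v = line.split(":", 1)
            else:
                raise InputError(f"config line not key=value: {line!r}")
            out[k.strip()] = v.strip()
    return out
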