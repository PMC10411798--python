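"""Positional candidate-gene annotation of distorted SNPs and regions.

Genes are looked up in a symmetric window (default +/- 250 kb) around each
SNP position using closed 1-based interval arithmetic; a gene whose interval
contains the SNP position itself is flagged ``overlapping``, any other hit in
the window is ``proximal``. Strand is ignored. Gene tables are read from BED
(0-based half-open, converted on input) or GFF3 (1-based inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import VariantRecord
from .scan import SnpTrdResult, TrdRegion


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    name: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")


def _norm_chrom(label) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(path, dialect: str | None = None) -> list[GeneInterval]:
    """Read genes from a BED or GFF3 file; dialect inferred from extension."""
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "bed" if suffix == ".bed" else "gff3" if suffix in (".gff", ".gff3") else None
        if dialect is None:
            raise ValueError(f"cannot infer gene-table dialect from {path.name!r}; pass dialect=")
    genes: list[GeneInterval] = []
    if dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs at least 3 columns")
        for i, row in df.iterrows():
            name = str(row[3]) if df.shape[1] > 3 else f"gene{i}"
            genes.append(
                GeneInterval(
                    gene_id=name,
                    name=name,
                    chrom=_norm_chrom(row[0]),
                    start_bp=int(row[1]) + 1,  # 0-based half-open -> 1-based closed
                    end_bp=int(row[2]),
                )
            )
    elif dialect == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", names=range(9))
        types = df[2].astype(str)
        if (types == "gene").any():
            df = df[types == "gene"]
        for i, row in df.iterrows():
            attrs = _parse_gff_attributes(str(row[8]))
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gene{i}"))
            genes.append(
                GeneInterval(
                    gene_id=gene_id,
                    name=attrs.get("Name", gene_id),
                    chrom=_norm_chrom(row[0]),
                    start_bp=int(row[3]),
                    end_bp=int(row[4]),
                )
            )
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    return genes


def annotate_snp(
    snp: VariantRecord,
    genes: list[GeneInterval],
    window_bp: int = 250_000,
) -> list[tuple[GeneInterval, str]]:
    """Genes intersecting ``[pos - window, pos + window]`` (closed intervals).

    Returns ``(gene, overlap_class)`` pairs where the class is
    ``"overlapping"`` when the gene contains the SNP position and
    ``"proximal"`` otherwise. An empty list with a warning is returned when
    the SNP's chromosome is absent from the gene table.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    chrom = _norm_chrom(snp.chrom)
    table_chroms = {g.chrom for g in genes}
    if genes and chrom not in table_chroms:
        warnings.warn(f"chromosome {chrom!r} absent from gene table", stacklevel=2)
        return []
    lo = max(1, snp.pos_bp - window_bp)
    hi = snp.pos_bp + window_bp
    hits = []
    for g in genes:
        if g.chrom != chrom or g.end_bp < lo or g.start_bp > hi:
            continue
        cls = "overlapping" if g.start_bp <= snp.pos_bp <= g.end_bp else "proximal"
        hits.append((g, cls))
    hits.sort(key=lambda gc: (gc[0].start_bp, gc[0].gene_id))
    return hits


def annotate_results(
    results: list[SnpTrdResult],
    regions: list[TrdRegion] | None,
    genes: list[GeneInterval],
    window_bp: int = 250_000,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-SNP and per-region gene annotation tables.

    Only SNPs passing the cascade are annotated. Returns the two tables and
    the total number of distinct genes hit (de-duplicated by ``gene_id``).
    """
    snp_rows = []
    distinct: set[str] = set()
    for r in results:
        if not r.passes_region_criteria:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hits = annotate_snp(r.variant, genes, window_bp)
        for g, cls in hits:
            distinct.add(g.gene_id)
            snp_rows.append(
                {
                    "snp_id": r.variant.id,
                    "chrom": r.variant.chrom,
                    "pos_bp": r.variant.pos_bp,
                    "pattern": r.pattern.label if r.pattern else "",
                    "gene_id": g.gene_id,
                    "gene_name": g.name,
                    "gene_start_bp": g.start_bp,
                    "gene_end_bp": g.end_bp,
                    "overlap_class": cls,
                }
            )
    region_rows = []
    for reg in regions or []:
        seen: set[str] = set()
        for g in genes:
            if g.chrom != _norm_chrom(reg.chrom):
                continue
            lo = max(1, reg.start_bp - window_bp)
            hi = reg.end_bp + window_bp
            if g.end_bp < lo or g.start_bp > hi or g.gene_id in seen:
                continue
            seen.add(g.gene_id)
            region_rows.append(
                {
                    "chrom": reg.chrom,
                    "start_bp": reg.start_bp,
                    "end_bp": reg.end_bp,
                    "pattern": reg.pattern,
                    "gene_id": g.gene_id,
                    "gene_name": g.name,
                }
            )
    snp_df = pd.DataFrame(
        snp_rows,
        columns=[
            "snp_id",
            "chrom",
            "pos_bp",
            "pattern",
            "gene_id",
            "gene_name",
            "gene_start_bp",
            "gene_end_bp",
            "overlap_class",
        ],
    )
    region_df = pd.DataFrame(
        region_rows, columns=["chrom", "start_bp", "end_bp", "pattern", "gene_id", "gene_name"]
    )
    return snp_df, region_df, len(distinct)
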