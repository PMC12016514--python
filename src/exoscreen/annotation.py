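"""Gene annotations: identity, chromosome, strand and TSS.

The TSS anchors every binding window in the pipeline, so annotations are
validated aggressively on load: coordinates are 1-based and positive,
strands are exactly ``+`` or ``-``, and gene ids are unique.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

import gffutils
import pandas as pd

__all__ = ["GeneAnnotation", "read_annotation", "read_chrom_sizes"]


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene: id, chromosome, strand and 1-based TSS coordinate."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start_codon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: TSS must be a positive 1-based coordinate")
        if self.start_codon is not None and self.start_codon < 1:
            raise ValueError(f"{self.gene_id}: start_codon must be positive")


_TSV_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start_codon"]


def _check_unique(genes: list[GeneAnnotation]) -> list[GeneAnnotation]:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)
    return genes


def _read_tsv(path: str) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    # Tolerate an optional header row naming the expected columns.
    if str(df.iloc[0, 0]).strip().lower() == "gene_id":
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 4:
        raise ValueError("annotation TSV needs columns gene_id, chrom, strand, tss")
    df.columns = _TSV_COLUMNS[: df.shape[1]]
    genes = []
    for row in df.itertuples(index=False):
        start_codon = None
        if len(row) > 4 and pd.notna(row[4]) and str(row[4]).strip():
            start_codon = int(row[4])
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                start_codon=start_codon,
            )
        )
    return _check_unique(genes)


def _read_gff3(path: str) -> list[GeneAnnotation]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # TSS is the 5' end of the gene feature: start on +, end on -.
        if feat.strand == "+":
            tss = feat.start
        elif feat.strand == "-":
            tss = feat.end
        else:
            raise ValueError(f"{gene_id}: strand must be '+' or '-', got {feat.strand!r}")
        genes.append(GeneAnnotation(gene_id=gene_id, chrom=feat.seqid, strand=feat.strand, tss=tss))
    return _check_unique(genes)


def read_annotation(path: str, format: Optional[str] = None) -> list[GeneAnnotation]:
    """Read gene annotations from a TSV or GFF3 file.

    TSV columns are ``gene_id, chrom, strand, tss[, start_codon]`` (1-based
    coordinates, tab-separated, optional header).  For GFF3, one record per
    ``gene`` feature is produced and the TSS is the strand-aware 5' end.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"tsv"`` or ``"gff3"``; inferred from the extension when omitted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "gff3" if ext in (".gff", ".gff3") else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    sizes = {str(c): int(s) for c, s in zip(df["chrom"], df["size"])}
    for chrom, size in sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {size}")
    return sizes


def write_annotation_tsv(genes: Iterable[GeneAnnotation], path: str) -> None:
    rows = [
        (g.gene_id, g.chrom, g.strand, g.tss, "" if g.start_codon is None else g.start_codon)
        for g in genes
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", header=False, index=False)
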