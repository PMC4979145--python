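"""Positional integration of GWAS hits with gene models and DEGs.

Gene models (1-based inclusive coordinates) come from GFF3.  Each
significant SNP gets a SNP-gene relation label with the precedence
UTR-3/UTR-5 > exon > intron inside a gene, upstream/downstream within a
strand-oriented window of the TSS/TES, otherwise intergenic with the
nearest gene named.  Flank capture collects every gene whose span
intersects the +/- flank window of a significant SNP, and the DEG
overlap is an inner join of the captured genes with the DEG table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "load_gff3",
    "write_gff3",
    "classify_snp_gene_relation",
    "flank_gene_capture",
    "gwas_deg_overlap",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        for lo, hi in self.exons + self.utr5 + self.utr3:
            if not (self.start <= lo <= hi <= self.end):
                raise ValueError(f"{self.gene_id}: feature outside gene span")


def load_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3 file via gffutils.

    Genes are taken from ``gene`` features; exons and UTRs are gathered
    from their children (``exon``, ``five_prime_UTR``,
    ``three_prime_UTR``).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons, utr5, utr3 = [], [], []
        for child in db.children(gene):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=str(gene.seqid),
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(sorted(exons)),
                utr5=tuple(sorted(utr5)),
                utr3=tuple(sorted(utr3)),
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon/UTR children)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start)):
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for kind, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for k, (lo, hi) in enumerate(ivs, 1):
                    fh.write(
                        f"{g.chrom}\tsim\t{kind}\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.{kind}{k};Parent={g.gene_id}\n"
                    )


def _in_any(pos: int, intervals) -> bool:
    return any(lo <= pos <= hi for lo, hi in intervals)


def classify_snp_gene_relation(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    near_bp: int = 5000,
) -> tuple[str | None, str]:
    """Label a SNP's relation to the nearest gene.

    Inside a gene the precedence is UTR-3/UTR-5 > exon > intron.  Outside
    every gene span the SNP is "upstream"/"downstream" of a gene whose
    strand-oriented TSS/TES lies within ``near_bp``; otherwise
    "intergenic" with the nearest gene by bp distance.  Ties are broken
    by the lexicographically smaller gene_id.  A chromosome with no
    annotated gene returns (None, "intergenic").
    """
    chrom_genes = sorted(
        (g for g in genes if g.chrom == str(chrom)), key=lambda g: g.gene_id
    )
    if not chrom_genes:
        return None, "intergenic"

    inside = [g for g in chrom_genes if g.start <= pos <= g.end]
    for g in inside:
        if _in_any(pos, g.utr3):
            return g.gene_id, "UTR-3"
        if _in_any(pos, g.utr5):
            return g.gene_id, "UTR-5"
    for g in inside:
        if _in_any(pos, g.exons):
            return g.gene_id, "exon"
    if inside:
        return inside[0].gene_id, "intron"

    best: tuple[int, str, str] | None = None  # (distance, gene_id, relation)
    for g in chrom_genes:
        if pos < g.start:
            dist = g.start - pos
            before_start = True
        else:
            dist = pos - g.end
            before_start = False
        if dist <= near_bp:
            if g.strand == "+":
                relation = "upstream" if before_start else "downstream"
            else:
                relation = "downstream" if before_start else "upstream"
            cand = (dist, g.gene_id, relation)
            if best is None or cand < best:
                best = cand
    if best is not None:
        return best[1], best[2]

    nearest = min(
        chrom_genes,
        key=lambda g: (g.start - pos if pos < g.start else pos - g.end, g.gene_id),
    )
    return nearest.gene_id, "intergenic"


def flank_gene_capture(
    snps: pd.DataFrame,
    genes: list[GeneModel],
    flank_kb: float = 50,
) -> pd.DataFrame:
    """Genes whose span intersects the +/- flank window of each SNP.

    ``snps`` columns: snp_id, chrom, pos.  Intervals are closed; the
    distance is 0 when the SNP lies inside the gene, otherwise the bp gap
    between the SNP and the nearer gene edge.  Output rows are sorted by
    (snp_id, gene_id).
    """
    if flank_kb <= 0:
        raise ValueError("flank_kb must be positive")
    flank = int(round(flank_kb * 1000))
    rows = []
    for snp in snps.itertuples(index=False):
        lo, hi = snp.pos - flank, snp.pos + flank
        for g in genes:
            if g.chrom != str(snp.chrom):
                continue
            if g.end < lo or g.start > hi:
                continue
            if g.start <= snp.pos <= g.end:
                dist = 0
            elif snp.pos < g.start:
                dist = g.start - snp.pos
            else:
                dist = snp.pos - g.end
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "chrom": snp.chrom,
                    "pos": snp.pos,
                    "gene_id": g.gene_id,
                    "distance_bp": int(dist),
                }
            )
    out = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "gene_id", "distance_bp"])
    if len(out):
        out = out.sort_values(["snp_id", "gene_id"]).reset_index(drop=True)
    return out


def gwas_deg_overlap(captured: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Inner join of flank-captured genes with the DEG table.

    One row per (gene, snp) pair carrying the distance, log2 fold change,
    q-value and DEG status; deterministic (gene_id, snp_id) order.  Only
    genes actually called DE (status != not_de) are reported.
    """
    de = degs[degs["status"] != "not_de"]
    merged = captured.merge(
        de[["gene_id", "log2fc", "q", "status"]], on="gene_id", how="inner"
    )
    cols = ["gene_id", "snp_id", "distance_bp", "log2fc", "q", "status"]
    merged = merged[cols].drop_duplicates(["gene_id", "snp_id"])
    return merged.sort_values(["gene_id", "snp_id"]).reset_index(drop=True)
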