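"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (read through cyvcf2, written as plain VCF 4.2
text) or PLINK text .ped/.map; phenotype records as CSV; counts, traits
and association tables as TSV.  The coded allele is always the VCF ALT
(PLINK allele "G"), so round-trips preserve dosages exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_ped_map",
    "read_ped_map",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT fields (REF=A, ALT=G)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.snps["chrom"]):
            length = int(G.snps.loc[G.snps["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples) + "\n")
        dosage = np.asarray(G.dosage)
        for j, snp in enumerate(G.snps.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else _GT[int(d)] for d in dosage[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix of ALT-allele dosages (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, chroms, positions = [], [], [], []
    for var in vcf:
        gts = var.genotype.array()
        dose = gts[:, 0:2].astype(float)
        dose[dose < 0] = np.nan
        rows.append(np.nansum(dose, axis=1) + np.where(np.isnan(dose).all(axis=1), np.nan, 0.0))
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(int(var.CHROM))
        positions.append(var.POS)
    dosage = np.array(rows, dtype=np.float32).T
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": positions})
    return GenotypeMatrix(dosage=dosage, samples=samples, snps=snps)


def write_ped_map(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK text .ped/.map (alleles A=REF, G=coded)."""
    prefix = Path(prefix)
    alleles = {0: "A A", 1: "A G", 2: "G G"}
    dosage = np.asarray(G.dosage)
    with prefix.with_suffix(".ped").open("w") as fh:
        for i, sample in enumerate(G.samples):
            geno = " ".join(
                "0 0" if np.isnan(d) else alleles[int(d)] for d in dosage[i]
            )
            fh.write(f"FAM1 {sample} 0 0 0 -9 {geno}\n")
    with prefix.with_suffix(".map").open("w") as fh:
        for snp in G.snps.itertuples(index=False):
            fh.write(f"{snp.chrom}\t{snp.snp_id}\t0\t{snp.pos}\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map; dosage counts the non-"A" allele."""
    prefix = Path(prefix)
    snps = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
    )[["snp_id", "chrom", "pos"]]
    samples, rows = [], []
    with prefix.with_suffix(".ped").open() as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            allele_pairs = parts[6:]
            dose = np.empty(len(allele_pairs) // 2, dtype=np.float32)
            for j in range(dose.size):
                a, b = allele_pairs[2 * j], allele_pairs[2 * j + 1]
                if a == "0" or b == "0":
                    dose[j] = np.nan
                else:
                    dose[j] = (a != "A") + (b != "A")
            rows.append(dose)
    return GenotypeMatrix(dosage=np.vstack(rows), samples=samples, snps=snps)


def write_phenotypes_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
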