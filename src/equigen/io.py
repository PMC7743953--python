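"""Readers and writers for the plain-text exchange formats.

Pedigrees travel as CSV (id,sire,dam; 0 = unknown); phenotype, score,
competition and EBV tables as TSV; genotypes as a PLINK-style transposed
text (one SNP per row: snp, chrom, pos, then one dosage column per
individual, NA for missing).  An optional VCF reader (biallelic sites, GT
field) is provided through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "read_table",
    "write_table",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
]


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp\tchrom\tpos\t" + "\t".join(geno.ids) + "\n")
        for (_, row), dose in zip(geno.snps.iterrows(), geno.dosages):
            vals = "\t".join("NA" if np.isnan(d) else str(int(d)) for d in dose)
            fh.write(f"{row['snp']}\t{row['chrom']}\t{row['pos']}\t{vals}\n")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    ids = list(frame.columns[3:])
    snps = frame[["snp", "chrom", "pos"]].copy()
    dosages = frame[ids].to_numpy(dtype=float)
    return GenotypeMatrix(snps, dosages, ids)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF, GT field only; others are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, dose = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gts == 3, 2.0, gts)
        d[gts == 2] = np.nan
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS)))
        dose.append(d)
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    return GenotypeMatrix(snps, np.array(dose), ids)
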