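"""Readers and writers for the pipeline's file formats.

Genotypes travel either as minimal GT-only VCF (interoperability) or as
a TSV dosage matrix (fixtures and round-trips); germination counts,
seed-lot phenotypes and all result tables are plain CSV with documented
headers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "read_genotype_file",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_germination_csv",
    "write_germination_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
]

log = logging.getLogger("seedlong")

GERMINATION_COLUMNS = ["accession", "dah", "storage_day", "n_sown", "n_germ"]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2, GT-only, one biallelic SNP per record."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(np.unique(genotypes.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(str(a) for a in genotypes.accessions)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(genotypes.n_snps):
            gts = [
                "./." if np.isnan(d) else _GT_CODE[int(round(d))]
                for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.snp_ids[j]}\t"
                f"{genotypes.ref[j]}\t{genotypes.alt[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (biallelic SNPs only).

    Multi-allelic records are dropped with a logged count.  GT fields
    map ./., 0/0, 0/1, 1/1 to missing, 0, 1, 2.  Duplicate SNP ids are
    an error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = np.array(vcf.samples, dtype=object)
    rows, ids, chroms, poss, refs, alts = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        vid = var.ID if var.ID not in (None, ".") else f"c{var.CHROM}_{var.POS}"
        ids.append(vid)
        chroms.append(int(str(var.CHROM).removeprefix("chr").removeprefix("Chr")))
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_multi:
        log.info("dropped %d multi-allelic records from %s", n_multi, path)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated SNP ids in {path}: {dupes[:5]}")
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(
        dosage=np.array(rows, dtype=float).T,
        accessions=samples,
        snp_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=int),
        pos=np.array(poss, dtype=int),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """TSV dosage matrix: snp/chrom/pos/ref/alt columns then one column
    per accession; missing calls written as NA."""
    genotypes.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["snp", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV {path} lacks columns {missing}")
    if df["snp"].duplicated().any():
        dupes = df.loc[df["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicated SNP ids in {path}: {dupes[:5]}")
    acc = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        dosage=df[acc].to_numpy(dtype=float).T,
        accessions=np.array(acc, dtype=object),
        snp_ids=df["snp"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=int),
        pos=df["pos"].to_numpy(dtype=int),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
    )


def read_genotype_file(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on declared or inferred format ('vcf' or 'tsv')."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_germination_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[GERMINATION_COLUMNS].to_csv(path, index=False)


def read_germination_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GERMINATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"germination CSV {path} lacks columns {missing}")
    bad = (df["n_germ"] > df["n_sown"]) | (df["n_germ"] < 0) | (df["storage_day"] < 0)
    if bad.any():
        raise ValueError(
            f"germination CSV {path}: {int(bad.sum())} rows violate "
            "0 <= n_germ <= n_sown, storage_day >= 0"
        )
    return df


def write_phenotype_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("accession", "maturity", "harvest_mc"):
        if col not in df.columns:
            raise ValueError(f"phenotype CSV {path} lacks column {col!r}")
    return df
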