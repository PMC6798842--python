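"""Accession x SNP dosage matrices and marker-level operations.

Dosages are additive allele counts in {0, 1, 2} with ``nan`` for missing
calls.  Inbred panels (the default produced by the simulator) carry only
{0, 2}.  Coordinates are 1-based, VCF/GFF3 convention, on chromosomes
numbered 1-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "filter_snps",
    "compute_kinship",
    "compute_pcs",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus marker metadata.

    Parameters
    ----------
    dosage : ndarray, shape (n_accessions, n_snps)
        Allele dosages as floats; ``nan`` marks a missing call.
    accessions, snp_ids : arrays of str
    chrom : ndarray of int
        Chromosome number per SNP (1-12).
    pos : ndarray of int
        1-based physical position per SNP, sorted within chromosome.
    ref, alt : arrays of str
        Reference / alternative alleles per SNP.
    subpop : optional ndarray of int
        Subpopulation label per accession (populated by the simulator).
    """

    dosage: np.ndarray
    accessions: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    subpop: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.accessions = np.asarray(self.accessions, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = self.dosage.shape
        if len(self.accessions) != n:
            raise ValueError("accession labels do not match dosage rows")
        for arr, name in ((self.snp_ids, "snp_ids"), (self.chrom, "chrom"),
                          (self.pos, "pos")):
            if len(arr) != m:
                raise ValueError(f"{name} does not match dosage columns")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.mean(np.isnan(self.dosage), axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alternative-allele frequency on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency on non-missing calls."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given SNP indices (order preserved)."""
        index = np.asarray(index)
        return replace(
            self,
            dosage=self.dosage[:, index],
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref, dtype=object)[index],
            alt=np.asarray(self.alt, dtype=object)[index],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if len(hits) == 0:
            raise KeyError(snp_id)
        return int(hits[0])

    def imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by per-SNP means."""
        d = self.dosage.copy()
        means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
        return d

    def to_frame(self) -> pd.DataFrame:
        """Marker table (snp, chrom, pos, ref, alt) plus one column per accession."""
        meta = pd.DataFrame(
            {
                "snp": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )
        dos = pd.DataFrame(self.dosage.T, columns=list(self.accessions))
        return pd.concat([meta, dos], axis=1)


def filter_snps(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Drop SNPs by missingness and minor allele frequency.

    A SNP is removed when its missing fraction exceeds ``max_missing`` or
    its MAF (computed on non-missing dosages) is below ``min_maf``; a MAF
    exactly equal to ``min_maf`` is retained (the filter removes
    frequencies strictly below the threshold).

    Raises
    ------
    ValueError
        If no SNP survives; the message reports counts per criterion.
    """
    miss = genotypes.missing_fraction()
    maf = genotypes.maf()
    bad_missing = miss > max_missing
    with np.errstate(invalid="ignore"):
        bad_maf = ~(maf >= min_maf)  # nan (all-missing SNP) counts as bad
    keep = ~(bad_missing | bad_maf)
    if not keep.any():
        raise ValueError(
            "all SNPs removed by filtering: "
            f"{int(bad_missing.sum())} failed missingness > {max_missing}, "
            f"{int(bad_maf.sum())} failed MAF < {min_maf}"
        )
    return genotypes.take_snps(np.flatnonzero(keep))


def compute_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """Centred cross-product (VanRaden) kinship matrix.

    Missing dosages are mean-imputed per SNP; with ``W`` the dosage matrix
    minus twice the allele frequency, ``K = W W' / sum(2 p (1-p))`` over
    polymorphic SNPs.  The result is symmetric and PSD up to rounding.
    """
    d = genotypes.imputed()
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship undefined: all SNPs are monomorphic")
    w = d[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    k = w @ w.T / denom
    return (k + k.T) / 2.0


def compute_pcs(genotypes: GenotypeMatrix, n_pcs: int = 5) -> np.ndarray:
    """Principal-component scores of the centred (mean-imputed) dosages.

    Returns an (n_accessions, n_pcs) score matrix; scores of distinct
    components are mutually orthogonal.
    """
    if n_pcs >= genotypes.n_accessions:
        raise ValueError(
            f"n_pcs={n_pcs} must be smaller than the number of accessions "
            f"({genotypes.n_accessions})"
        )
    d = genotypes.imputed()
    d = d - d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]
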