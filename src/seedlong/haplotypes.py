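"""Favourable-allele classification at association peaks and combination
effects on seed longevity (p50).

At each peak's lead SNP, the homozygote class with the higher mean trait
value defines the favourable allele; accessions homozygous for it are
"favourable" at that locus, heterozygotes and the other homozygote are
"unfavourable", missing calls are "unknown".  Accessions classified at
every locus form combination groups whose mean p50 is compared with the
all-unfavourable reference group (enhancement %); single-locus allele
effects are expressed relative to the unfavourable-class mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import Peak
from .genotypes import GenotypeMatrix

__all__ = [
    "HaplotypeGroupTable",
    "assign_haplotype_states",
    "estimate_haplotype_effects",
]

FAVOURABLE = "favourable"
UNFAVOURABLE = "unfavourable"
UNKNOWN = "unknown"


@dataclass
class HaplotypeGroupTable:
    """Combination-group and per-locus allele-effect report."""

    groups: pd.DataFrame  # combination, n, mean_p50, enhancement_pct, ratio
    loci: pd.DataFrame    # locus, favourable_allele, freq_pct, allele_effect_pct
    reference_mean: float
    n_classified: int
    min_group_n: int

    def summary(self) -> str:
        lines = [
            "Haplotype-combination effects on p50",
            "-" * 44,
            f"fully classified accessions: {self.n_classified}",
            f"reference (all-unfavourable) mean p50: {self.reference_mean:.3f} d",
            "",
            self.groups.to_string(index=False),
            "",
            self.loci.to_string(index=False),
        ]
        return "\n".join(lines)


def assign_haplotype_states(
    genotypes: GenotypeMatrix,
    peaks: list[Peak],
    trait: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Per-accession favourable/unfavourable/unknown state at each peak locus.

    Returns a DataFrame indexed by accession with one column per retained
    locus (lead-SNP id); the favourable allele per locus is stored in
    ``df.attrs['favourable_allele']``.  Monomorphic or uninformative
    (equal class means) lead SNPs drop their locus with a warning.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    y = np.asarray(trait, dtype=float)
    states: dict[str, np.ndarray] = {}
    fav_alleles: dict[str, str] = {}
    for pk in peaks:
        j = genotypes.snp_index(pk.lead_snp)
        d = genotypes.dosage[:, j]
        hom_alt = d == 2
        hom_ref = d == 0
        if not hom_alt.any() or not hom_ref.any():
            warnings.warn(
                f"locus {pk.lead_snp} dropped: lead SNP monomorphic among "
                "homozygote classes",
                stacklevel=2,
            )
            continue
        mean_alt = float(np.nanmean(y[hom_alt]))
        mean_ref = float(np.nanmean(y[hom_ref]))
        if mean_alt == mean_ref:
            warnings.warn(
                f"locus {pk.lead_snp} dropped: equal class means (uninformative)",
                stacklevel=2,
            )
            continue
        fav_is_alt = mean_alt > mean_ref
        fav_dosage = 2 if fav_is_alt else 0
        col = np.where(
            np.isnan(d), UNKNOWN, np.where(d == fav_dosage, FAVOURABLE, UNFAVOURABLE)
        )
        states[pk.lead_snp] = col
        allele = genotypes.alt[j] if fav_is_alt else genotypes.ref[j]
        fav_alleles[pk.lead_snp] = str(allele)
    if not states:
        raise ValueError("no informative loci among the peaks")
    df = pd.DataFrame(states, index=list(genotypes.accessions))
    df.attrs["favourable_allele"] = fav_alleles
    return df


def estimate_haplotype_effects(
    states: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    min_group_n: int = 3,
) -> HaplotypeGroupTable:
    """Combination-group means, enhancement ratios and per-locus effects.

    enhancement% of group g = 100 * (mean(g) - mean(ref)) / mean(ref),
    with the all-unfavourable combination as reference (enhancement 0 by
    definition).  Groups smaller than ``min_group_n`` are suppressed from
    the report (the reference is always kept).  Per-locus allele effect%
    = 100 * (mean favourable - mean unfavourable) / mean unfavourable on
    all accessions classified at that locus; the favourable-allele
    frequency is the % of classified accessions in the favourable state.
    """
    y = pd.Series(np.asarray(trait, dtype=float), index=states.index)
    loci = list(states.columns)
    classified = states[(states != UNKNOWN).all(axis=1)]
    ref_key = tuple([UNFAVOURABLE] * len(loci))
    combos = classified.apply(tuple, axis=1)
    group_means = y.loc[classified.index].groupby(combos).agg(["size", "mean"])
    if ref_key not in group_means.index:
        raise ValueError(
            "reference group (unfavourable at all loci) is empty; consider "
            "an alternative reference combination"
        )
    ref_mean = float(group_means.loc[[ref_key], "mean"].iloc[0])
    rows = []
    for combo, (n, mean) in group_means.iterrows():
        enh = 100.0 * (mean - ref_mean) / ref_mean
        rows.append(
            {
                "combination": "/".join("F" if s == FAVOURABLE else "U" for s in combo),
                "n_favourable_loci": sum(s == FAVOURABLE for s in combo),
                "n": int(n),
                "mean_p50": float(mean),
                "enhancement_pct": float(enh),
                "ratio": float(enh) / 100.0,
            }
        )
    groups = pd.DataFrame(rows)
    keep = (groups["n"] >= min_group_n) | (
        groups["combination"] == "/".join(["U"] * len(loci))
    )
    groups = (
        groups[keep]
        .sort_values(["n_favourable_loci", "enhancement_pct"], ascending=False)
        .reset_index(drop=True)
    )
    locus_rows = []
    fav_map = states.attrs.get("favourable_allele", {})
    for locus in loci:
        col = states[locus]
        known = col != UNKNOWN
        fav = col == FAVOURABLE
        mean_fav = float(y[fav].mean())
        mean_unf = float(y[known & ~fav].mean())
        locus_rows.append(
            {
                "locus": locus,
                "favourable_allele": fav_map.get(locus, ""),
                "favourable_freq_pct": 100.0 * float(fav.sum()) / float(known.sum()),
                "allele_effect_pct": 100.0 * (mean_fav - mean_unf) / mean_unf,
            }
        )
    return HaplotypeGroupTable(
        groups=groups,
        loci=pd.DataFrame(locus_rows),
        reference_mean=ref_mean,
        n_classified=len(classified),
        min_group_n=min_group_n,
    )
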