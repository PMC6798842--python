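"""End-to-end driver: germination counts -> viability fits -> trait table
-> dual-model GWAS -> peaks -> haplotype effects -> summary statistics.

Every stage writes its table into the output directory as it completes,
so a failing stage leaves the earlier results on disk; a machine-readable
manifest records the seed, package versions and the analysis switches in
effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    DEFAULT_MERGE_DISTANCE,
    DEFAULT_THRESHOLD,
    AssociationStudy,
    annotate_peaks,
)
from .genotypes import GenotypeMatrix, compute_kinship, filter_snps
from .haplotypes import assign_haplotype_states, estimate_haplotype_effects
from .io import read_genotype_file, read_germination_csv, read_phenotype_csv
from .summarystats import (
    correlation_matrix,
    descriptive_table,
    maturity_paired_tests,
    sequential_harvest_regression,
)
from .viability import fit_common_slope, fit_probit_survival, select_best_lot

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "fit_germination_table"]

log = logging.getLogger("seedlong")

#: traits scanned by default; harvest MC is a covariate for Ki and p50
#: but not for the slope trait
DEFAULT_TRAITS = ("p50_38dah", "ki_38dah", "slope_38dah", "p50_max")
MC_COVARIATE_TRAITS = ("p50_38dah", "ki_38dah", "p50_max")


@dataclass
class PipelineConfig:
    """Paths, switches and seed for a full pipeline run."""

    germination_csv: str
    phenotype_csv: str
    genotype_file: str
    output_dir: str
    gff3: str | None = None
    genotype_format: str | None = None
    traits: tuple[str, ...] = DEFAULT_TRAITS
    mc_covariate: bool = True
    n_pcs: int = 5
    max_missing: float = 0.20
    min_maf: float = 0.05
    threshold: float = DEFAULT_THRESHOLD
    merge_distance: int = DEFAULT_MERGE_DISTANCE
    min_group_n: int = 3
    rng_seed: int = 0
    threads: int = 1  # accepted for interface compatibility; all code is
    # single-threaded so results never depend on it

    def validate(self) -> None:
        for p in (self.germination_csv, self.phenotype_csv, self.genotype_file,
                  self.gff3):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if self.threshold <= 0 or self.min_maf < 0 or self.max_missing < 0:
            raise ValueError("thresholds must be positive")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def fit_germination_table(germ: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (accession, maturity) lot and derive per-accession traits.

    Returns (fits, traits): ``fits`` has one row per lot with Ki, slope,
    sigma, p50, SEs and diagnostics plus the common-slope F-test result
    per accession; ``traits`` has one row per accession with the 38-DAH
    parameters, the maximum-p50 lot and its maturity.
    """
    fit_rows = []
    trait_rows = []
    for acc, grp in germ.groupby("accession", sort=True):
        lots = {}
        fits = {}
        for dah, sub in grp.groupby("dah"):
            t = sub["storage_day"].to_numpy(float)
            sown = sub["n_sown"].to_numpy(int)
            g = sub["n_germ"].to_numpy(int)
            lots[int(dah)] = (t, sown, g)
            fits[int(dah)] = fit_probit_survival(
                t, sown, g, accession=str(acc), maturity=int(dah)
            )
        common = None
        if sum(f.status == "ok" for f in fits.values()) >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    common = fit_common_slope(lots)
            except ValueError:
                common = None
        for dah, f in fits.items():
            fit_rows.append(
                {
                    "accession": acc,
                    "maturity": dah,
                    "ki": f.ki,
                    "slope": f.slope,
                    "sigma": f.sigma,
                    "p50": f.p50,
                    "se_ki": f.se_ki,
                    "se_slope": f.se_slope,
                    "se_p50": f.se_p50,
                    "residual_deviance": f.residual_deviance,
                    "df": f.df,
                    "n_points_used": f.n_points_used,
                    "truncated_from": f.truncated_from,
                    "status": f.status,
                    "common_slope_accepted": (
                        common.constraint_accepted if common else np.nan
                    ),
                    "common_slope_p": common.p_value if common else np.nan,
                }
            )
        row = {"accession": acc}
        f38 = fits.get(38)
        if f38 is not None and f38.status == "ok":
            row.update(
                p50_38dah=f38.p50, ki_38dah=f38.ki, slope_38dah=f38.slope
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                best_m, best = select_best_lot(fits)
            row.update(p50_max=best.p50, ki_max=best.ki, slope_max=best.slope,
                       best_maturity=best_m)
        except ValueError:
            pass
        trait_rows.append(row)
    return pd.DataFrame(fit_rows), pd.DataFrame(trait_rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a bundle of in-memory results."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "read-inputs"
    try:
        germ = read_germination_csv(config.germination_csv)
        pheno = read_phenotype_csv(config.phenotype_csv)
        gm = read_genotype_file(config.genotype_file, config.genotype_format)
        log.info("inputs: %d germination rows, %d phenotype rows, %d x %d genotypes",
                 len(germ), len(pheno), gm.n_accessions, gm.n_snps)

        stage = "viability-fits"
        fits, traits = fit_germination_table(germ)
        fits.to_csv(outdir / "fits.csv", index=False)
        n_ok = int((fits["status"] == "ok").sum())
        log.info("viability: %d/%d lots fitted", n_ok, len(fits))
        bundle["fits"] = fits

        stage = "trait-table"
        mc38 = (
            pheno[pheno["maturity"] == 38]
            .set_index("accession")["harvest_mc"]
            .rename("harvest_mc_38dah")
        )
        traits = traits.set_index("accession").join(mc38).reset_index()
        traits = traits.set_index("accession").reindex(list(gm.accessions)).reset_index()
        traits.to_csv(outdir / "traits.csv", index=False)
        bundle["traits"] = traits

        stage = "snp-filter"
        gm_f = filter_snps(gm, config.max_missing, config.min_maf)
        log.info("filter: %d of %d SNPs retained", gm_f.n_snps, gm.n_snps)
        kinship = compute_kinship(gm_f)

        stage = "association"
        scans = {}
        all_peaks = []
        for trait in config.traits:
            if trait not in traits.columns:
                continue
            y = traits[trait].to_numpy(float)
            ok = np.isfinite(y)
            if ok.sum() < 30:
                log.warning("trait %s: too few fitted accessions, skipped", trait)
                continue
            sub = gm_f.take_snps(np.arange(gm_f.n_snps))
            sub.dosage = sub.dosage[ok]
            sub.accessions = sub.accessions[ok]
            cov = None
            if config.mc_covariate and trait in MC_COVARIATE_TRAITS:
                mc = traits.loc[ok, "harvest_mc_38dah"].to_numpy(float)
                mc = np.where(np.isfinite(mc), mc, np.nanmean(mc))
                cov = pd.DataFrame({"harvest_mc": mc})
            study = AssociationStudy(
                sub, y[ok], trait_name=trait, covariates=cov,
                n_pcs=config.n_pcs, kinship=kinship[np.ix_(ok, ok)],
            )
            res = study.fit()
            res.table.to_csv(outdir / f"assoc_{trait}.csv", index=False)
            scans[trait] = res
            peaks = res.call_peaks(config.threshold, config.merge_distance)
            all_peaks.extend(peaks)
            log.info("scan %s: lambda GLM %.3f, MLM %.3f, %d peak(s)",
                     trait, res.lambda_glm, res.lambda_mlm, len(peaks))
        bundle["scans"] = scans
        bundle["peaks"] = all_peaks
        pd.DataFrame([dataclasses.asdict(p) for p in all_peaks]).to_csv(
            outdir / "peaks.csv", index=False
        )

        stage = "gene-annotation"
        if config.gff3 and all_peaks:
            genes = annotate_peaks(all_peaks, config.gff3)
            gene_rows = [
                {"lead_snp": k, **g} for k, gs in genes.items() for g in gs
            ]
            pd.DataFrame(gene_rows).to_csv(outdir / "peak_genes.csv", index=False)
            bundle["peak_genes"] = genes

        stage = "haplotype-effects"
        p50_peaks = [p for p in all_peaks if p.trait in ("p50_max", "p50_38dah")]
        if p50_peaks:
            trait_col = "p50_max" if any(
                p.trait == "p50_max" for p in p50_peaks
            ) else "p50_38dah"
            y = traits.set_index("accession").reindex(
                list(gm_f.accessions)
            )[trait_col].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                states = assign_haplotype_states(gm_f, p50_peaks, y)
                table = estimate_haplotype_effects(states, y, config.min_group_n)
            table.groups.to_csv(outdir / "haplotype_groups.csv", index=False)
            table.loci.to_csv(outdir / "haplotype_loci.csv", index=False)
            bundle["haplotypes"] = table

        stage = "summary-statistics"
        # covariate files may carry their own parameter columns (e.g. a
        # truth table); the fitted values take precedence in the stats
        pheno_cov = pheno.drop(
            columns=[c for c in ("ki", "slope", "sigma", "p50", "log_p50", "subpop")
                     if c in pheno.columns]
        )
        lot_table = pheno_cov.merge(
            fits[fits["status"] == "ok"][
                ["accession", "maturity", "ki", "slope", "p50"]
            ],
            on=["accession", "maturity"],
            how="inner",
        )
        trait_cols = [
            c for c in ("harvest_mc", "hundred_seed_weight", "ki", "slope", "p50")
            if c in lot_table.columns
        ]
        descriptive_table(lot_table[trait_cols]).to_csv(
            outdir / "descriptive.csv", index=False
        )
        r, pmat, stars_df = correlation_matrix(lot_table[trait_cols])
        r.to_csv(outdir / "correlations_r.csv")
        pmat.to_csv(outdir / "correlations_p.csv")
        stars_df.to_csv(outdir / "correlations_stars.csv")
        maturity_paired_tests(pheno).to_csv(outdir / "paired_tests.csv", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            harvest = sequential_harvest_regression(lot_table)
        harvest.points.to_csv(outdir / "harvest_regression_points.csv", index=False)
        pd.DataFrame(
            [
                {"branch": b, **(f or {})}
                for b, f in (("dried", harvest.dried), ("wetted", harvest.wetted))
            ]
        ).to_csv(outdir / "harvest_regression.csv", index=False)
        bundle["harvest_regression"] = harvest

        stage = "manifest"
        manifest = {
            "package": "seedlong",
            "version": __version__,
            "rng_seed": config.rng_seed,
            "config": {
                k: v for k, v in dataclasses.asdict(config).items()
            },
            "decisions": {
                "kinship": "centred cross-product (VanRaden)",
                "mlm": "EMMAX-style single null-model REML variance ratio",
                "f_test_denominator": (
                    "heterogeneity factor max(unconstrained deviance/df, 1)"
                ),
                "mc_covariate_traits": list(MC_COVARIATE_TRAITS),
                "truncation": "retain from last running-maximum proportion",
                "haplotype_state": "lead-SNP homozygote class",
                "allele_effect_denominator": "unfavourable-class mean",
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return bundle
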