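"""File formats.

Genotypes travel as VCF (GT hard calls, DS dosages, INFO/RSQ imputation
quality) or as a dosage TSV (rows = SNPs, columns = samples, ``NA``
missing) with a sidecar annotation TSV.  Expression is a TSV with the probe
id in the first column and one column per sample.  All coordinates are
1-based inclusive; dosages are oriented to the minor allele as estimated
from the data itself.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ExpressionMatrix, GenotypeMatrix, ValidationError
from .gwas import GENOME_WIDE_P


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF with GT (hard-callable dosages) and DS fields.

    REF is the major allele, ALT the minor allele, so the ALT dosage in the
    file equals the stored minor-allele dosage.  Fractional dosages yield
    ``./.`` GT with the DS field carrying the value; INFO holds RSQ when an
    imputation quality is annotated.
    """
    path = Path(path)
    samples = list(G.sample_ids)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation rsq">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        order = G.snps.sort_values(["chrom", "pos"]).index
        for snp in order:
            row = G.snps.loc[snp]
            dos = G.dosage[snp].to_numpy(dtype=float)
            rsq = row["imputation_rsq"]
            info = f"RSQ={rsq:.4f}" if pd.notna(rsq) else "."
            fields = []
            for d in dos:
                if np.isnan(d):
                    fields.append("./.:.")
                    continue
                if float(d).is_integer():
                    k = int(d)
                    gt = ["0/0", "0/1", "1/1"][k]
                else:
                    gt = "./."
                fields.append(f"{gt}:{d:g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['major_allele']}\t"
                f"{row['minor_allele']}\t.\t.\t{info}\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a minor-allele dosage matrix.

    Dosages come from DS when present, else from GT ALT-allele counts.
    The minor allele is determined from the data: if the ALT frequency
    exceeds 0.5 the dosage is flipped to count REF copies and the allele
    labels swap accordingly.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, pos, minor, major, mafs, rsqs, rows = [], [], [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(f"multi-allelic or missing ALT at {var.ID or var.POS}")
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the FORMAT header
            ds = None
        if ds is not None:
            d = ds[:, 0].astype(float)
            d = np.where(d < 0, np.nan, d)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = var.gt_types.astype(float)
            d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f_alt = np.nanmean(d) / 2.0
        if f_alt > 0.5:
            d = 2.0 - d
            mn, mj = var.REF, var.ALT[0]
            maf = 1.0 - f_alt
        else:
            mn, mj = var.ALT[0], var.REF
            maf = f_alt
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
        minor.append(mn)
        major.append(mj)
        mafs.append(maf)
        rsq = var.INFO.get("RSQ")
        rsqs.append(float(rsq) if rsq is not None else np.nan)
        rows.append(d)
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "minor_allele": minor,
            "major_allele": major,
            "maf": mafs,
            "imputation_rsq": rsqs,
        },
        index=pd.Index(ids, name="snp"),
    )
    dosage = pd.DataFrame(
        np.array(rows).T, index=pd.Index(samples, name="sample"), columns=snps.index
    )
    return GenotypeMatrix(dosage=dosage, snps=snps)


def write_genotypes_tsv(G: GenotypeMatrix, dosage_path, anno_path) -> None:
    """Dosage TSV (rows = SNPs, columns = samples, NA missing) + annotation TSV."""
    G.dosage.T.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%.6g")
    G.snps.to_csv(anno_path, sep="\t", na_rep="NA")


def read_genotypes_tsv(dosage_path, anno_path) -> GenotypeMatrix:
    dosage = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA"]).T
    dosage.index.name = "sample"
    snps = pd.read_csv(anno_path, sep="\t", index_col=0, na_values=["NA"])
    snps.index.name = "snp"
    snps["chrom"] = snps["chrom"].astype(str)
    return GenotypeMatrix(dosage=dosage, snps=snps)


def write_expression_tsv(E: ExpressionMatrix, expr_path, anno_path=None) -> None:
    """Expression TSV: first column probe id, remaining columns samples."""
    E.values.T.to_csv(expr_path, sep="\t", float_format="%.8g")
    if anno_path is not None:
        E.probes.to_csv(anno_path, sep="\t")


def read_expression_tsv(expr_path, anno_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0).T
    values.index.name = "sample"
    if values.index.has_duplicates or values.columns.has_duplicates:
        raise ValidationError("duplicate sample or probe ids in expression TSV")
    bad = values.columns[~values.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValidationError(f"non-numeric expression values in probes: {list(bad)[:5]}")
    probes = pd.read_csv(anno_path, sep="\t", index_col=0)
    probes.index.name = "probe"
    probes["chrom"] = probes["chrom"].astype(str)
    for flag in ("contains_snp", "ambiguous_mapping"):
        probes[flag] = probes[flag].astype(bool)
    return ExpressionMatrix(values=values, probes=probes.loc[values.columns])


def write_covariates_tsv(covars: pd.DataFrame, path) -> None:
    covars.to_csv(path, sep="\t")


def read_covariates_tsv(path) -> pd.DataFrame:
    covars = pd.read_csv(path, sep="\t", index_col=0)
    covars.index.name = "sample"
    if covars.index.has_duplicates:
        raise ValidationError("duplicate sample ids in covariate TSV")
    return covars


def write_gwas_tsv(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path, enforce_genome_wide: bool = True) -> pd.DataFrame:
    """GWAS list TSV: snp, chrom (or chr), pos, trait, reported_gene, p_gwas.

    Rows above the genome-wide significance cutoff (5e-8) are dropped with
    a warning, per the source-significance invariant.
    """
    gwas = pd.read_csv(path, sep="\t")
    gwas = gwas.rename(columns={"chr": "chrom"})
    required = {"snp", "trait", "p_gwas"}
    missing = required - set(gwas.columns)
    if missing:
        raise ValidationError(f"GWAS TSV missing columns: {sorted(missing)}")
    if enforce_genome_wide:
        bad = gwas["p_gwas"] > GENOME_WIDE_P
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} GWAS rows above the genome-wide "
                f"significance cutoff {GENOME_WIDE_P:g}"
            )
            gwas = gwas[~bad].copy()
    if "chrom" in gwas:
        gwas["chrom"] = gwas["chrom"].astype(str)
    return gwas


def intersect_samples(G: GenotypeMatrix, E: ExpressionMatrix, covars: pd.DataFrame):
    """Reduce all three inputs to their common samples (logged by callers)."""
    common = [s for s in G.sample_ids if s in set(E.sample_ids) & set(covars.index)]
    if not common:
        raise ValidationError("no samples shared across genotype/expression/covariates")
    return G.subset(samples=common), E.subset(samples=common), covars.loc[common]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
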