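"""Core in-memory containers shared across the pipeline.

Genotypes are stored as minor-allele dosages (0..2, possibly fractional after
imputation, NaN = missing) in a samples x SNPs DataFrame, expression as
log2-scale intensities in a samples x probes DataFrame.  Annotations are plain
DataFrames indexed by SNP / probe id so they slice together with the matrices.
All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_ANNOTATION_COLUMNS = [
    "chrom", "pos", "minor_allele", "major_allele", "maf", "imputation_rsq",
]

PROBE_ANNOTATION_COLUMNS = [
    "gene", "chrom", "strand", "tss", "gene_start", "gene_end",
    "contains_snp", "ambiguous_mapping",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with its SNP annotation.

    Attributes
    ----------
    dosage : DataFrame, samples x SNPs, values in [0, 2] or NaN (missing).
    snps : DataFrame indexed by SNP id with columns
        ``chrom, pos, minor_allele, major_allele, maf, imputation_rsq``.
        ``maf`` is the frequency assigned/estimated for the minor allele;
        ``imputation_rsq`` is NaN for directly genotyped SNPs.
    """

    dosage: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosage.columns) != list(self.snps.index):
            raise ValidationError("dosage columns and SNP annotation index differ")
        if self.dosage.columns.has_duplicates or self.dosage.index.has_duplicates:
            raise ValidationError("duplicate SNP or sample ids in genotype matrix")
        vals = self.dosage.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 2:
                raise ValidationError("dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> pd.Series:
        """Per-sample fraction of non-missing genotypes."""
        return self.dosage.notna().mean(axis=1)

    def empirical_maf(self) -> pd.Series:
        """Minor-allele frequency recomputed from the current samples.

        The frequency of the allele counted by the dosage column is
        ``mean(dosage)/2``; the minor-allele frequency is its fold onto
        [0, 0.5].
        """
        f = self.dosage.mean(axis=0, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        d = self.dosage
        a = self.snps
        if samples is not None:
            d = d.loc[list(samples)]
        if snps is not None:
            d = d[list(snps)]
            a = a.loc[list(snps)]
        return GenotypeMatrix(dosage=d, snps=a)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values (samples x probes) with probe annotation."""

    values: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.probes.index):
            raise ValidationError("expression columns and probe annotation index differ")
        if self.values.columns.has_duplicates or self.values.index.has_duplicates:
            raise ValidationError("duplicate probe or sample ids in expression matrix")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, samples=None, probes=None) -> "ExpressionMatrix":
        v = self.values
        a = self.probes
        if samples is not None:
            v = v.loc[list(samples)]
        if probes is not None:
            v = v[list(probes)]
            a = a.loc[list(probes)]
        return ExpressionMatrix(values=v, probes=a)


def validate_probe_annotation(probes: pd.DataFrame) -> None:
    """Check the TSS/strand/gene-bound conventions of a probe annotation."""
    missing = [c for c in PROBE_ANNOTATION_COLUMNS if c not in probes.columns]
    if missing:
        raise ValidationError(f"probe annotation missing columns: {missing}")
    if (probes["gene_start"] > probes["gene_end"]).any():
        raise ValidationError("gene_start must be <= gene_end")
    plus = probes["strand"] == "+"
    if not (probes.loc[plus, "tss"] == probes.loc[plus, "gene_start"]).all():
        raise ValidationError("on the + strand the TSS must equal gene_start")
    if not (probes.loc[~plus, "tss"] == probes.loc[~plus, "gene_end"]).all():
        raise ValidationError("on the - strand the TSS must equal gene_end")


@dataclass
class QcReport:
    """Bookkeeping for the genotype QC cascade.

    ``removed_samples`` / ``removed_snps`` map each removed id to the single
    primary reason (the first rule in the cascade that caught it).
    """

    sample_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    snp_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_samples: dict = field(default_factory=dict)
    removed_snps: dict = field(default_factory=dict)
    retained_samples: list = field(default_factory=list)
    retained_snps: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"unit": "sample", "id": k, "reason": v} for k, v in self.removed_samples.items()
        ] + [
            {"unit": "snp", "id": k, "reason": v} for k, v in self.removed_snps.items()
        ]
        return pd.DataFrame(rows, columns=["unit", "id", "reason"])
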