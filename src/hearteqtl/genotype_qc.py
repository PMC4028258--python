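"""Sample- and SNP-level genotype quality control.

The cascade mirrors standard array-QC practice: per-sample call rate
(< 0.95 removed), duplicate/related pairs by mean identity-by-state
(> 0.95), heterozygosity outliers (robust z-scores, Benjamini-Hochberg at
FDR 0.01), population stratification by Manhattan-distance hierarchical
clustering confirmed with PCA, then per-SNP filters: minor allele frequency
>= 0.15 (recomputed on the retained samples; at n = 129 this implies an
expected n*maf^2 ~ 3 minor-allele homozygotes, the minimum for a meaningful
additive fit) and imputation quality rsq >= 0.30 for imputed SNPs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, QcReport, ValidationError

#: dosage bands treated as uncertain when hard-calling imputed genotypes
UNCERTAIN_BANDS = ((0.25, 0.75), (1.25, 1.75))


def hard_calls(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to 0/1/2; uncertain fractional dosages become NaN."""
    d = np.asarray(dosage, dtype=float)
    out = np.round(d)
    for lo, hi in UNCERTAIN_BANDS:
        out = np.where((d > lo) & (d < hi), np.nan, out)
    return out


def call_rate_filter(G: GenotypeMatrix, min_rate: float = 0.95) -> list:
    """Samples with a fraction of non-missing genotypes < ``min_rate``."""
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValidationError("empty genotype matrix")
    rates = G.call_rate()
    return list(rates.index[rates < min_rate])


def heterozygosity(G: GenotypeMatrix) -> pd.Series:
    """Per-sample heterozygous fraction over confidently hard-called SNPs."""
    H = hard_calls(G.dosage.to_numpy())
    called = ~np.isnan(H)
    het = (H == 1) & called
    with np.errstate(invalid="ignore"):
        frac = het.sum(axis=1) / called.sum(axis=1)
    return pd.Series(frac, index=G.sample_ids)


def robust_z(x: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores (MAD scaled to the normal SD)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    return (x - med) / mad


def heterozygosity_outliers(G: GenotypeMatrix, fdr: float = 0.01) -> list:
    """Flag samples with extreme heterozygosity.

    Two-sided p-values from robust z-scores (median / scaled MAD) of the
    per-sample heterozygous fraction, Benjamini-Hochberg at ``fdr``.  When
    the MAD is zero the z-scores fall back to mean/SD with a warning.
    """
    if G.n_samples < 10:
        raise ValidationError("heterozygosity outlier detection needs >=10 samples")
    het = heterozygosity(G)
    x = het.to_numpy()
    mad = np.median(np.abs(x - np.median(x))) * 1.4826
    if mad == 0:
        warnings.warn("heterozygosity MAD is zero; falling back to mean/SD z-scores")
        sd = x.std(ddof=1)
        if sd == 0:
            return []
        z = (x - x.mean()) / sd
    else:
        z = robust_z(x)
    p = 2 * norm.sf(np.abs(z))
    reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return list(het.index[reject])


def ibs_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise mean identity-by-state over hard-called genotypes.

    Per SNP, IBS between two samples is ``1 - |g1 - g2| / 2``; the pairwise
    score averages over SNPs called in both.  Symmetric with unit diagonal.
    """
    if G.n_samples < 2:
        raise ValidationError("IBS needs >=2 samples")
    H = hard_calls(G.dosage.to_numpy())
    n = H.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(H[i] - H[i + 1 :])  # NaN where either sample is uncalled
        sim = 1.0 - diff / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(sim, axis=1)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return pd.DataFrame(out, index=G.sample_ids, columns=G.sample_ids)


def ibs_relatedness_filter(G: GenotypeMatrix, max_ibs: float = 0.95) -> list:
    """Remove one member of each pair with mean IBS > ``max_ibs``.

    The member with the lower genotype call rate is dropped; ties go to the
    later sample in matrix order.
    """
    ibs = ibs_matrix(G)
    rates = G.call_rate()
    removed: list = []
    ids = list(G.sample_ids)
    arr = ibs.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if arr[i, j] > max_ibs:
                a, b = ids[i], ids[j]
                if a in removed or b in removed:
                    continue
                drop = b if rates[b] <= rates[a] else a
                removed.append(drop)
    return removed


def manhattan_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Mean absolute dosage difference, pairwise-excluding missing calls."""
    D = G.dosage.to_numpy(dtype=float)
    n = D.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(D[i] - D[i + 1 :])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(diff, axis=1)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return out


def stratification_outliers(
    G: GenotypeMatrix,
    min_cluster_frac: float = 0.25,
    cut_scale: float = 1.05,
):
    """Detect genetically stratified samples.

    Average-linkage hierarchical clustering on the Manhattan (mean absolute
    dosage difference) distance matrix; the tree is cut at ``cut_scale``
    times the median pairwise distance and clusters smaller than
    ``min_cluster_frac * n`` are flagged.  The first two principal
    components of the mean-imputed, centered dosage matrix are returned for
    visual confirmation.  Deterministic.
    """
    n = G.n_samples
    if n < 10:
        raise ValidationError("stratification detection needs >=10 samples")
    dist = manhattan_distance_matrix(G)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    cut = cut_scale * float(np.median(condensed))
    assignment = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(assignment).value_counts()
    small = set(sizes.index[sizes < min_cluster_frac * n])
    flagged = [sid for sid, a in zip(G.sample_ids, assignment) if a in small]

    D = G.dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(D, axis=0)
    filled = np.where(np.isnan(D), col_mean, D)
    keep = filled.std(axis=0) > 0
    pcs = PCA(n_components=2, svd_solver="full").fit_transform(
        filled[:, keep] - filled[:, keep].mean(axis=0)
    )
    pc_df = pd.DataFrame(pcs, index=G.sample_ids, columns=["PC1", "PC2"])
    return flagged, pc_df


def maf_filter(G: GenotypeMatrix, min_maf: float = 0.15) -> list:
    """Retain SNPs whose recomputed MAF is >= ``min_maf`` (boundary inclusive)."""
    maf = G.empirical_maf()
    return list(maf.index[maf >= min_maf])


def expected_hom_count(n: int, maf: float) -> float:
    """Expected minor-allele homozygotes under HWE: ``n * maf**2``."""
    if not (0 <= maf <= 0.5):
        raise ValidationError("maf must lie in [0, 0.5]")
    if n <= 0:
        raise ValidationError("n must be positive")
    return n * maf**2


def imputation_rsq_filter(snps: pd.DataFrame, cutoff: float = 0.30) -> list:
    """Retain SNPs with imputation rsq >= ``cutoff``; genotyped SNPs (no rsq) pass."""
    rsq = snps["imputation_rsq"]
    valid = rsq.dropna()
    if ((valid < 0) | (valid > 1)).any():
        raise ValidationError("imputation rsq must lie in [0, 1]")
    keep = rsq.isna() | (rsq >= cutoff)
    return list(snps.index[keep])


def run_genotype_qc(
    G: GenotypeMatrix,
    min_call_rate: float = 0.95,
    max_ibs: float = 0.95,
    het_fdr: float = 0.01,
    min_cluster_frac: float = 0.25,
    strat_cut_scale: float = 1.05,
    min_maf: float = 0.15,
    rsq_cutoff: float = 0.30,
):
    """Full sample/SNP QC cascade.

    Order: call rate -> IBS -> heterozygosity -> stratification, then SNP
    filters (MAF recomputed on the retained samples, imputation rsq).
    Each removed id records the single (first) rule that caught it.

    Returns (clean GenotypeMatrix, QcReport).
    """
    report = QcReport()
    report.sample_stats = pd.DataFrame(
        {"call_rate": G.call_rate(), "heterozygosity": heterozygosity(G)}
    )

    current = G
    for sid in call_rate_filter(current, min_call_rate):
        report.removed_samples[sid] = "call_rate"
    current = current.subset(
        samples=[s for s in current.sample_ids if s not in report.removed_samples]
    )

    for sid in ibs_relatedness_filter(current, max_ibs):
        report.removed_samples[sid] = "ibs"
    current = current.subset(
        samples=[s for s in current.sample_ids if s not in report.removed_samples]
    )

    for sid in heterozygosity_outliers(current, het_fdr):
        report.removed_samples[sid] = "heterozygosity"
    current = current.subset(
        samples=[s for s in current.sample_ids if s not in report.removed_samples]
    )

    flagged, pcs = stratification_outliers(current, min_cluster_frac, strat_cut_scale)
    for sid in flagged:
        report.removed_samples[sid] = "stratification"
    current = current.subset(
        samples=[s for s in current.sample_ids if s not in report.removed_samples]
    )
    report.sample_stats = report.sample_stats.join(pcs, how="left")

    maf = current.empirical_maf()
    keep_maf = set(maf_filter(current, min_maf))
    keep_rsq = set(imputation_rsq_filter(current.snps, rsq_cutoff))
    for snp in current.snp_ids:
        if snp not in keep_maf:
            report.removed_snps[snp] = "maf"
        elif snp not in keep_rsq:
            report.removed_snps[snp] = "imputation_rsq"
    retained_snps = [s for s in current.snp_ids if s not in report.removed_snps]
    current = current.subset(snps=retained_snps)
    current.snps = current.snps.copy()
    current.snps["maf"] = maf.loc[retained_snps]

    report.snp_stats = pd.DataFrame({"maf": maf, "rsq": G.snps["imputation_rsq"]})
    report.retained_samples = list(current.sample_ids)
    report.retained_snps = list(current.snp_ids)
    return current, report
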