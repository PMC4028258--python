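"""Overlay of trait-associated GWAS SNPs with the eQTL scan.

GWAS SNPs (genome-wide significant in their source studies, p <= 5e-8) are
LD-pruned into independent loci, tested against every measured transcript
with the same additive model as the scan, flagged at a Bonferroni threshold
of 0.05 / (n_loci x n_transcripts), and their count of nominally
significant (p <= 0.05) eQTL loci Q is compared against matched random SNP
sets (same cardinality, MAF bin and distance-to-nearest-TSS bin per SNP) to
give a fold-enrichment score and an empirical p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, ValidationError
from .mapping import ScanConfig, _components, build_design, fit_eqtl, ld_r2, run_scan

GENOME_WIDE_P = 5e-8

#: default matching bins: MAF width 0.05; distance-to-nearest-TSS edges
MAF_BIN_WIDTH = 0.05
TSS_DIST_EDGES = (0.0, 1e4, 1e5, 1e6, np.inf)


def bonferroni_threshold(alpha: float, n_loci: int, n_transcripts: int):
    """Per-test threshold alpha / (n_loci * n_transcripts).

    Returns (threshold, n_tests).
    """
    if n_loci <= 0 or n_transcripts <= 0 or alpha <= 0:
        raise ValidationError("alpha and counts must be positive")
    n_tests = n_loci * n_transcripts
    return alpha / n_tests, n_tests


def prune_gwas_loci(
    gwas: pd.DataFrame,
    G: GenotypeMatrix | None = None,
    r2_table: pd.DataFrame | None = None,
    r2: float = 0.6,
) -> list:
    """Single-linkage LD clusters over the GWAS SNP list.

    LD comes from the genotype matrix where available, else from a supplied
    symmetric pairwise ``r2_table``; a SNP absent from both is kept as its
    own locus with a warning.  Returns a list of loci, each a dict with
    ``snps`` (members) and ``lead`` (lowest source p, tie: first listed).
    """
    snps = list(pd.unique(gwas["snp"]))
    if not snps:
        return []
    known = set(G.snp_ids) if G is not None else set()
    table = r2_table if r2_table is not None else pd.DataFrame()

    def r2_fn(i, j):
        a, b = snps[i], snps[j]
        if G is not None and a in known and b in known:
            return ld_r2(G.dosage[a], G.dosage[b])
        if a in table.index and b in table.columns:
            return float(table.loc[a, b])
        return 0.0

    orphan = [
        s
        for s in snps
        if s not in known and not (s in table.index and s in table.columns)
    ]
    if orphan:
        warnings.warn(f"no LD source for GWAS SNPs {orphan}; each kept as its own locus")

    chrom_of = {}
    for s in snps:
        rows = gwas[gwas["snp"] == s]
        chrom_of[s] = str(rows["chrom"].iloc[0]) if "chrom" in gwas else "NA"
    labels = _components(
        snps, [chrom_of[s] for s in snps], None, r2_fn, r2
    )
    p_of = (
        gwas.groupby("snp")["p_gwas"].min()
        if "p_gwas" in gwas
        else pd.Series(1.0, index=snps)
    )
    loci = []
    for lab in np.unique(labels):
        members = [snps[i] for i in np.where(labels == lab)[0]]
        lead = min(members, key=lambda s: (p_of.get(s, 1.0), snps.index(s)))
        loci.append({"snps": members, "lead": lead})
    loci.sort(key=lambda L: p_of.get(L["lead"], 1.0))
    return loci


def test_gwas_snps(
    loci: list,
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covars: pd.DataFrame,
    cfg: ScanConfig | None = None,
    alpha: float = 0.05,
    nominal_p: float = 0.05,
    count_level: str = "locus",
):
    """Test every locus SNP against all transcripts.

    Returns (table, nominal_table, Q, threshold) where ``table`` holds one
    row per SNP-transcript test with a ``genome_wide`` flag at the
    Bonferroni threshold for n_loci x n_transcripts tests, ``nominal_table``
    keeps rows at p <= ``nominal_p``, and ``Q`` counts nominal eQTL hits at
    ``count_level`` ("locus": a locus counts once if any member SNP hits
    any transcript; "pair": every nominal SNP-transcript row counts).
    """
    cfg = cfg or ScanConfig()
    if count_level not in ("locus", "pair"):
        raise ValidationError("count_level must be 'locus' or 'pair'")
    if not loci:
        empty = pd.DataFrame(
            columns=["locus", "snp", "probe", "gene", "beta", "se", "p", "genome_wide"]
        )
        return empty, empty.copy(), 0, float("nan")
    kept_loci = []
    for locus in loci:
        present = [s for s in locus["snps"] if s in G.snp_ids]
        if not present:
            warnings.warn(
                f"locus led by {locus['lead']} has no SNP in the genotype data; excluded"
            )
            continue
        kept_loci.append({**locus, "snps": present})
    if not kept_loci:
        raise ValidationError("no GWAS locus SNP present in the genotype data")

    threshold, n_tests = bonferroni_threshold(
        alpha, len(kept_loci), len(E.probe_ids)
    )
    X = build_design(covars.loc[G.sample_ids])
    rows = []
    for li, locus in enumerate(kept_loci, start=1):
        for snp in locus["snps"]:
            d = G.dosage[snp]
            for probe in E.probe_ids:
                fit = fit_eqtl(E.values[probe], d, X)
                rows.append(
                    {
                        "locus": li,
                        "snp": snp,
                        "probe": probe,
                        "gene": E.probes.loc[probe, "gene"],
                        "beta": fit["beta"],
                        "se": fit["se"],
                        "p": fit["p"],
                    }
                )
    table = pd.DataFrame(rows)
    table["genome_wide"] = table["p"] < threshold
    nominal = table[table["p"] <= nominal_p].copy()
    if count_level == "locus":
        Q = int(nominal["locus"].nunique())
    else:
        Q = int(len(nominal))
    return table, nominal, Q, threshold


def annotate_tss_distance(snps: pd.DataFrame, probes: pd.DataFrame) -> pd.Series:
    """Distance from each SNP to the nearest TSS on its chromosome (bp).

    SNPs on chromosomes without any probe get +inf (they fall in the last
    proximity bin).
    """
    out = pd.Series(np.inf, index=snps.index)
    for chrom, group in probes.groupby(probes["chrom"].astype(str)):
        tss = np.sort(group["tss"].to_numpy(dtype=float))
        mask = snps["chrom"].astype(str) == chrom
        if not mask.any() or tss.size == 0:
            continue
        pos = snps.loc[mask, "pos"].to_numpy(dtype=float)
        idx = np.searchsorted(tss, pos)
        left = np.abs(pos - tss[np.clip(idx - 1, 0, tss.size - 1)])
        right = np.abs(tss[np.clip(idx, 0, tss.size - 1)] - pos)
        out.loc[mask] = np.minimum(left, right)
    return out


def _bin_ids(maf: pd.Series, tss_dist: pd.Series, maf_width: float, dist_edges):
    maf_bin = np.floor(np.clip(maf.to_numpy(dtype=float), 0, 0.5 - 1e-12) / maf_width)
    dist_bin = np.searchsorted(np.asarray(dist_edges)[1:-1], tss_dist.to_numpy(dtype=float),
                               side="right")
    return pd.Series(
        [f"maf{int(a)}_d{int(b)}" for a, b in zip(maf_bin, dist_bin)], index=maf.index
    )


def matched_random_sets(
    pool: pd.DataFrame,
    target_ids,
    n_sets: int,
    seed: int,
    maf_bin_width: float = MAF_BIN_WIDTH,
    dist_edges=TSS_DIST_EDGES,
) -> list:
    """Random SNP sets matched SNP-by-SNP on MAF and TSS-proximity bins.

    ``pool`` is a SNP annotation with columns ``maf`` and ``tss_dist``
    covering both the candidate SNPs and the targets.  Each returned set
    has the target's cardinality, each drawn SNP shares its counterpart's
    MAF bin (width ``maf_bin_width``) and distance bin (``dist_edges``),
    and sampling is without replacement within a set.  Deterministic per
    seed.
    """
    target_ids = list(target_ids)
    missing = [t for t in target_ids if t not in pool.index]
    if missing:
        raise ValidationError(f"target SNPs absent from the pool: {missing}")
    bins = _bin_ids(pool["maf"], pool["tss_dist"], maf_bin_width, dist_edges)
    target_bins = bins.loc[target_ids]
    need = target_bins.value_counts()
    members: dict = {b: bins.index[bins == b].to_numpy() for b in need.index}
    for b, k in need.items():
        if len(members[b]) < k:
            raise ValidationError(
                f"matching bin {b} holds {len(members[b])} pool SNPs but {k} are needed; "
                "widen the MAF or proximity bins"
            )
    rng = np.random.default_rng([int(seed), 6])
    sets = []
    for _ in range(n_sets):
        chosen = []
        for b, k in need.items():
            chosen.extend(rng.choice(members[b], size=int(k), replace=False))
        sets.append(list(chosen))
    return sets


@dataclass
class EnrichmentResult:
    """Observed vs matched-null nominal eQTL counts."""

    Q: int
    Q_i: np.ndarray = field(repr=False)
    fold: float = float("nan")
    p_emp: float = float("nan")
    n_sets: int = 0
    n_substituted: int = 0  # null sets with Q_i = 0 replaced by the half-count


def enrichment(Q: int, Q_i, eps: float = 0.5) -> EnrichmentResult:
    """Fold-enrichment and empirical p for the GWAS-locus eQTL count.

    fold = mean_i Q / max(Q_i, eps)  (eps = 0.5 half-count where Q_i = 0);
    p_emp = (#{i : Q_i >= Q} + 1) / (n_sets + 1), so ties count against
    enrichment and p_emp is never zero.
    """
    if Q is None or Q < 0:
        raise ValidationError("Q must be a non-negative count")
    Q_i = np.asarray(Q_i, dtype=float)
    if Q_i.size < 1:
        raise ValidationError("enrichment needs at least one null set")
    denom = np.where(Q_i > 0, Q_i, eps)
    fold = float(np.mean(Q / denom))
    p_emp = float((np.sum(Q_i >= Q) + 1) / (Q_i.size + 1))
    return EnrichmentResult(
        Q=int(Q),
        Q_i=Q_i,
        fold=fold,
        p_emp=p_emp,
        n_sets=int(Q_i.size),
        n_substituted=int(np.sum(Q_i == 0)),
    )


def nominal_snp_counts(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covars: pd.DataFrame,
    nominal_p: float = 0.05,
) -> pd.Series:
    """Per-SNP count of transcripts associating at p <= nominal_p.

    Precomputing this once makes enrichment over many random sets cheap
    at either counting level: a locus-level Q_i adds 1 per SNP with a
    positive count, a pair-level Q_i sums the counts directly.
    """
    X = build_design(covars.loc[G.sample_ids]).to_numpy(dtype=float)
    n, k = X.shape
    df = n - (k + 1)
    Y = E.values.to_numpy(dtype=float)
    D = G.dosage.to_numpy(dtype=float)
    has_nan = np.isnan(D).any(axis=0)
    pinv = np.linalg.pinv(X)
    Yres = Y - X @ (pinv @ Y)
    Dres = D - X @ (pinv @ np.nan_to_num(D))
    Dres[:, has_nan] = np.nan
    d2 = np.einsum("ij,ij->j", np.nan_to_num(Dres), np.nan_to_num(Dres))
    from scipy import stats as _st

    counts = np.zeros(D.shape[1], dtype=int)
    for pj in range(Y.shape[1]):
        num = np.nan_to_num(Dres).T @ Yres[:, pj]
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = num / d2
            rss = np.maximum(Yres[:, pj] @ Yres[:, pj] - beta * num, 0.0)
            se = np.sqrt(rss / df / d2)
            t = np.abs(beta / se)
        p = 2 * _st.t.sf(t, df)
        counts += np.nan_to_num(p, nan=1.0) <= nominal_p
    design = build_design(covars.loc[G.sample_ids])
    for sj in np.where(has_nan)[0]:
        counts[sj] = sum(
            fit_eqtl(Y[:, pj], D[:, sj], design)["p"] <= nominal_p
            for pj in range(Y.shape[1])
        )
    return pd.Series(counts, index=G.snp_ids)


def nominal_snp_indicator(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covars: pd.DataFrame,
    nominal_p: float = 0.05,
) -> pd.Series:
    """Per-SNP flag: does any transcript associate at p <= nominal_p?"""
    return nominal_snp_counts(G, E, covars, nominal_p) > 0
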