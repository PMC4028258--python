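"""The eQTL association core.

Per SNP-transcript pair an additive linear model is fitted by ordinary
least squares:

    expression = intercept + beta * dosage + covariates + error

with ``beta`` the log2 expression change per copy of the minor allele and a
two-sided p-value from the t distribution.  Pairs are cis when the SNP lies
within 1 Mb of the transcript's TSS on the same chromosome (boundary
inclusive) and trans otherwise.  Cis tests are corrected with Storey
q-values over the complete set of cis p-values (q <= 0.05 significant);
trans tests are first floored at p < 5e-8 (Bonferroni for one million
independent tests) and then corrected with Benjamini-Hochberg.  Significant
SNPs are LD-pruned into clusters of pairwise-linked SNPs (single-linkage
over r^2 > 0.6), each reported by its most significant member.

The genome-wide scan is organized per probe with vectorized statistics; the
result is contractually identical to fitting every pair with
:func:`fit_eqtl` (Frisch-Waugh-Lovell residualization gives the exact OLS
coefficient, SE and t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GenotypeMatrix, ValidationError

P_FLOOR = 1e-300  # numeric floor so downstream corrections never see p == 0


@dataclass
class ScanConfig:
    """Thresholds of the genome-wide scan."""

    cis_window: int = 1_000_000
    cis_fdr: float = 0.05
    trans_p_floor: float = 5e-8
    trans_fdr: float = 0.05
    ld_r2: float = 0.6

    def validate(self) -> None:
        if self.cis_window <= 0:
            raise ValidationError("cis_window must be positive")
        for name in ("cis_fdr", "trans_fdr"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not (0 < self.trans_p_floor < 1):
            raise ValidationError("trans_p_floor must lie in (0, 1)")
        if not (0 <= self.ld_r2 <= 1):
            raise ValidationError("ld_r2 must lie in [0, 1]")


def build_design(covars: pd.DataFrame) -> pd.DataFrame:
    """Covariate design: intercept, age, and indicator-coded sex and center.

    Categorical covariates are coded against the first observed level.
    """
    parts = [pd.Series(1.0, index=covars.index, name="intercept")]
    if "age" in covars:
        parts.append(covars["age"].astype(float))
    for cat in ("sex", "center"):
        if cat in covars:
            dummies = pd.get_dummies(covars[cat].astype(str), prefix=cat, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def fit_eqtl(y, d, X=None):
    """OLS of expression on dosage with optional covariates.

    Parameters
    ----------
    y, d : array-like expression and dosage vectors (NaNs dropped pairwise).
    X : optional covariate design (without intercept column duplication; an
        intercept is added if absent).

    Returns
    -------
    dict with ``beta, se, t, p, df, n`` for the dosage coefficient.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    if X is None:
        M = np.ones((len(y), 1))
        names = ["intercept"]
    else:
        M = np.asarray(X, dtype=float)
        names = list(X.columns) if hasattr(X, "columns") else [
            f"x{i}" for i in range(M.shape[1])
        ]
        if not np.any(np.all(M == M[0:1, :], axis=0) & (M[0] != 0)):
            M = np.column_stack([np.ones(len(y)), M])
            names = ["intercept"] + names
    keep = ~(np.isnan(y) | np.isnan(d) | np.isnan(M).any(axis=1))
    y, d, M = y[keep], d[keep], M[keep]
    n = len(y)
    design = np.column_stack([M, d])
    k = design.shape[1]
    if n <= k:
        raise ValidationError(f"need more samples ({n}) than design columns ({k})")
    if np.var(d) == 0:
        raise ValidationError("dosage has zero variance")
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        for j in range(1, M.shape[1] + 1):
            if np.linalg.matrix_rank(M[:, :j]) < j:
                raise ValidationError(f"collinear covariate column: {names[j - 1]}")
        raise ValidationError("dosage is collinear with the covariates")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - k
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = P_FLOOR if beta != 0 else 1.0
    else:
        t = beta / se
        p = max(2 * stats.t.sf(abs(t), df), P_FLOOR)
    return {"beta": beta, "se": se, "t": float(t), "p": float(p), "df": df, "n": n}


def signed_distance(
    snp_pos: int,
    gene_start: int,
    gene_end: int,
    strand: str,
    snp_chrom=None,
    gene_chrom=None,
):
    """Transcription-direction-aware signed SNP-to-gene distance.

    Inside the gene body the distance is 0 ("inside").  Upstream SNPs
    (before the TSS in transcription direction) get a negative distance
    measured from the TSS; downstream SNPs (past the gene end in
    transcription direction) get a positive distance measured from the far
    gene boundary.

    Returns (distance_bp, label) with label in {"inside", "upstream",
    "downstream"}.  Raises for different chromosomes: a distance must not
    be requested across chromosomes.
    """
    if snp_chrom is not None and gene_chrom is not None and str(snp_chrom) != str(gene_chrom):
        raise ValidationError("signed distance undefined across chromosomes")
    if gene_start > gene_end:
        raise ValidationError("gene_start must be <= gene_end")
    if strand not in ("+", "-"):
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    if gene_start <= snp_pos <= gene_end:
        return 0, "inside"
    tss = gene_start if strand == "+" else gene_end
    if strand == "+":
        if snp_pos < gene_start:
            return int(snp_pos - tss), "upstream"
        return int(snp_pos - gene_end), "downstream"
    if snp_pos > gene_end:
        return int(tss - snp_pos), "upstream"
    return int(gene_start - snp_pos), "downstream"


def classify_relation(snp_chrom, snp_pos, probe_chrom, tss, cis_window=1_000_000) -> str:
    """cis iff same chromosome and |snp_pos - tss| <= cis_window (inclusive)."""
    if str(snp_chrom) == str(probe_chrom) and abs(int(snp_pos) - int(tss)) <= cis_window:
        return "cis"
    return "trans"


def bh_stepup(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, boolean rejection set)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def storey_pi0(p, lambdas=None) -> float:
    """Storey's pi0: proportion of true nulls, cubic-smoothed over a lambda grid."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_hat = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_hat, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return min(max(pi0, 1e-8), 1.0)


def storey_qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    ``q(i) = min over p(j) >= p(i) of pi0 * m * p(j) / rank(j)``; with
    ``pi0 = 1`` this is exactly the Benjamini-Hochberg adjusted p-value.
    pi0 is estimated on a lambda grid (0.05..0.95 step 0.05) with a cubic
    smoother evaluated at the largest lambda, clamped to (0, 1].  Fewer
    than 100 p-values give too noisy a pi0 estimate, so pi0 is fixed at 1
    with a warning (BH fallback).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            warnings.warn("fewer than 100 p-values: pi0 fixed at 1 (BH fallback)")
            pi0 = 1.0
        else:
            pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ld_r2(d1, d2) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    keep = ~(np.isnan(d1) | np.isnan(d2))
    if keep.sum() < 2:
        raise ValidationError("ld_r2 needs >=2 complete pairs")
    a, b = d1[keep], d2[keep]
    if np.var(a) == 0 or np.var(b) == 0:
        warnings.warn("zero-variance dosage vector: r2 undefined, returning 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdCluster:
    """A set of significant SNPs pairwise reachable through r2 links."""

    cluster_id: int
    snp_ids: list
    top_snp: str
    records: pd.DataFrame = field(repr=False, default=None)

    def representative_records(self) -> pd.DataFrame:
        """Lowest-p record per transcript among the member SNPs."""
        idx = self.records.groupby("probe")["p"].idxmin()
        return self.records.loc[idx]


def _components(snp_ids, chroms, positions, r2_fn, threshold):
    """Single-linkage components over r2 > threshold edges, per chromosome."""
    n = len(snp_ids)
    rows, cols = [], []
    by_chrom: dict = {}
    for i, c in enumerate(chroms):
        by_chrom.setdefault(c, []).append(i)
    for idxs in by_chrom.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                if r2_fn(i, j) > threshold:
                    rows.append(i)
                    cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def ld_prune(
    records: pd.DataFrame,
    G: GenotypeMatrix,
    r2_threshold: float = 0.6,
) -> list:
    """Group significant SNPs into independent LD clusters.

    ``records`` is a table of significant associations with at least
    columns ``snp, probe, p``.  SNPs linked by r2 > ``r2_threshold`` (same
    chromosome) merge transitively; each cluster's top SNP is its member
    with the lowest p (ties broken by smaller genomic position).

    Returns a list of :class:`LdCluster`, ordered by their top SNP's p.
    """
    if len(records) == 0:
        return []
    snp_ids = list(pd.unique(records["snp"]))
    anno = G.snps.loc[snp_ids]
    dosage = G.dosage[snp_ids].to_numpy(dtype=float)

    def r2_fn(i, j):
        return ld_r2(dosage[:, i], dosage[:, j])

    labels = _components(
        snp_ids, anno["chrom"].tolist(), anno["pos"].tolist(), r2_fn, r2_threshold
    )
    best_p = records.groupby("snp")["p"].min()
    clusters = []
    for lab in np.unique(labels):
        members = [snp_ids[i] for i in np.where(labels == lab)[0]]
        ranked = sorted(members, key=lambda s: (best_p[s], int(anno.loc[s, "pos"])))
        top = ranked[0]
        recs = records[records["snp"].isin(members)].copy()
        clusters.append(LdCluster(cluster_id=-1, snp_ids=members, top_snp=top, records=recs))
    clusters.sort(key=lambda c: best_p[c.top_snp])
    for i, c in enumerate(clusters):
        c.cluster_id = i + 1
    return clusters


@dataclass
class ScanResult:
    """Output of :func:`run_scan`."""

    records: pd.DataFrame  # significant associations
    cis_pvalues: pd.DataFrame  # all cis pairs: snp, probe, p, q
    n_tests: int = 0
    n_cis_tests: int = 0
    n_trans_tests: int = 0
    cis_p_threshold: float = float("nan")  # largest cis p with q <= cis_fdr
    pi0: float = float("nan")


def _align_samples(G: GenotypeMatrix, E: ExpressionMatrix, covars: pd.DataFrame):
    g, e, c = set(G.sample_ids), set(E.sample_ids), set(covars.index)
    if g != e or g != c:
        missing = sorted((g ^ e) | (g ^ c))
        raise ValidationError(f"sample ids not aligned across inputs; mismatches: {missing}")
    order = list(G.sample_ids)
    return E.subset(samples=order), covars.loc[order]


def _pair_stats(yres: np.ndarray, Dres: np.ndarray, d2: np.ndarray, df: int):
    """Vectorized OLS stats of one residualized probe against many SNPs."""
    num = Dres.T @ yres
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / d2
        rss = yres @ yres - beta * num
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / d2)
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    p = np.maximum(2 * stats.t.sf(np.abs(t), df), P_FLOOR)
    p = np.where(se > 0, p, np.where(beta != 0, P_FLOOR, 1.0))
    return beta, se, t, p


def run_scan(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covars: pd.DataFrame,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Genome-wide eQTL scan: every SNP x transcript pair.

    Cis pairs are corrected with Storey q-values over all cis p-values and
    kept at q <= ``cis_fdr``; trans pairs are floored at
    p < ``trans_p_floor`` and BH-corrected at ``trans_fdr``.  Significant
    records carry effect sizes, MAF, alleles, relation and the signed
    distance to the gene.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    E, covars = _align_samples(G, E, covars)
    X = build_design(covars).to_numpy(dtype=float)
    n, k = X.shape
    df = n - (k + 1)
    if df <= 0:
        raise ValidationError("not enough samples for the covariate design")

    Y = E.values.to_numpy(dtype=float)
    D = G.dosage.to_numpy(dtype=float)
    has_nan = np.isnan(D).any(axis=0)

    # residualize everything on the covariates once (exact OLS via FWL)
    XtX_inv_Xt = np.linalg.pinv(X)
    Yres = Y - X @ (XtX_inv_Xt @ Y)
    Dres = D.copy()
    Dres[:, ~has_nan] = D[:, ~has_nan] - X @ (XtX_inv_Xt @ D[:, ~has_nan])
    d2 = np.einsum("ij,ij->j", np.nan_to_num(Dres), np.nan_to_num(Dres))

    snp_chrom = G.snps["chrom"].astype(str).to_numpy()
    snp_pos = G.snps["pos"].to_numpy(dtype=int)
    probes = E.probes
    covar_design = build_design(covars)

    cis_rows = []
    trans_hits = []
    n_cis = n_trans = 0
    for pj, pid in enumerate(E.probe_ids):
        prow = probes.loc[pid]
        cis_mask = (snp_chrom == str(prow["chrom"])) & (
            np.abs(snp_pos - int(prow["tss"])) <= cfg.cis_window
        )
        n_cis += int(cis_mask.sum())
        n_trans += int((~cis_mask).sum())
        beta, se, t, p = _pair_stats(Yres[:, pj], Dres, d2, df)
        # slow exact path for SNPs with missing dosages
        if has_nan.any():
            for sj in np.where(has_nan)[0]:
                fit = fit_eqtl(Y[:, pj], D[:, sj], covar_design)
                beta[sj], se[sj], t[sj], p[sj] = fit["beta"], fit["se"], fit["t"], fit["p"]
        cis_idx = np.where(cis_mask)[0]
        if cis_idx.size:
            cis_rows.append(
                pd.DataFrame(
                    {
                        "snp": G.snp_ids[cis_idx],
                        "probe": pid,
                        "beta": beta[cis_idx],
                        "se": se[cis_idx],
                        "t": t[cis_idx],
                        "p": p[cis_idx],
                    }
                )
            )
        trans_idx = np.where(~cis_mask & (p < cfg.trans_p_floor))[0]
        for sj in trans_idx:
            trans_hits.append(
                {
                    "snp": G.snp_ids[sj],
                    "probe": pid,
                    "beta": beta[sj],
                    "se": se[sj],
                    "t": t[sj],
                    "p": p[sj],
                }
            )

    cis = (
        pd.concat(cis_rows, ignore_index=True)
        if cis_rows
        else pd.DataFrame(columns=["snp", "probe", "beta", "se", "t", "p"])
    )
    pi0 = float("nan")
    if len(cis):
        if len(cis) >= 100:
            pi0 = storey_pi0(cis["p"].to_numpy())
            cis["q"] = storey_qvalues(cis["p"].to_numpy(), pi0=pi0)
        else:
            cis["q"] = storey_qvalues(cis["p"].to_numpy())
            pi0 = 1.0
    else:
        cis["q"] = []

    sig_cis = cis[cis["q"] <= cfg.cis_fdr].copy()
    sig_cis["relation"] = "cis"
    cis_p_threshold = float(sig_cis["p"].max()) if len(sig_cis) else float("nan")

    trans = pd.DataFrame(trans_hits, columns=["snp", "probe", "beta", "se", "t", "p"])
    if len(trans):
        p_adj, reject = bh_stepup(trans["p"].to_numpy(), alpha=cfg.trans_fdr)
        trans["q"] = p_adj
        trans = trans[reject].copy()
    else:
        trans["q"] = []
    trans["relation"] = "trans"

    frames = [f for f in (sig_cis, trans) if len(f)]
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = sig_cis.iloc[0:0].copy()
    records = _annotate_records(records, G, probes, cfg)
    records = records.sort_values("p", kind="stable").reset_index(drop=True)

    return ScanResult(
        records=records,
        cis_pvalues=cis,
        n_tests=n_cis + n_trans,
        n_cis_tests=n_cis,
        n_trans_tests=n_trans,
        cis_p_threshold=cis_p_threshold,
        pi0=pi0,
    )


def _annotate_records(records, G, probes, cfg) -> pd.DataFrame:
    """Attach gene, MAF, alleles and the signed distance to each record."""
    if len(records) == 0:
        for col in ["gene", "chrom", "pos", "maf", "minor_allele", "major_allele",
                    "distance", "position_label"]:
            records[col] = []
        return records
    maf = G.empirical_maf()
    out = []
    for _, r in records.iterrows():
        snp = G.snps.loc[r["snp"]]
        prow = probes.loc[r["probe"]]
        same_chrom = str(snp["chrom"]) == str(prow["chrom"])
        if same_chrom:
            dist, label = signed_distance(
                int(snp["pos"]), int(prow["gene_start"]), int(prow["gene_end"]),
                str(prow["strand"]),
            )
        else:
            dist, label = np.nan, "other_chromosome"
        out.append(
            {
                **r,
                "gene": prow["gene"],
                "chrom": snp["chrom"],
                "pos": int(snp["pos"]),
                "maf": float(maf[r["snp"]]),
                "minor_allele": snp["minor_allele"],
                "major_allele": snp["major_allele"],
                "distance": dist,
                "position_label": label,
            }
        )
    return pd.DataFrame(out)
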