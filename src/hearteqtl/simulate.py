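"""Synthetic cohort generator.

Produces genotype, expression, annotation and covariate data with the
statistical structure the downstream analysis assumes: Hardy-Weinberg
genotypes with block-local LD, log2-scale expression with planted additive
cis/trans effects and covariate structure, Y-chromosome probes carrying no
signal in females (they anchor the detection threshold), and injectable QC
defects with ground-truth labels.

LD is produced by Markov allele copying along a block: within a block each
haplotype allele is copied from the previous SNP with probability
``ld_decay`` and redrawn from Bernoulli(MAF) otherwise, so the dosage
correlation between SNPs i and j in one block is ``ld_decay**|i-j|`` and
r2 decays geometrically while HWE marginals are preserved (every SNP in a
block shares the block's MAF).  Blocks are independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, ValidationError

#: Tissue-collection centers and their cohort weights (154-sample cohort:
#: Szeged 79, Nashville 46, Miami 30, Sydney 25 of 180 collected).
CENTERS = ("Szeged", "Nashville", "Miami", "Sydney")
CENTER_WEIGHTS = (79, 46, 30, 25)


@dataclass
class PlantedEffect:
    """A single additive genetic effect on one probe.

    ``beta`` is the log2 expression change per copy of the minor allele.
    """

    snp_id: str
    probe_id: str
    beta: float
    kind: str = "cis"  # "cis" | "trans"

    def __post_init__(self) -> None:
        if self.kind not in ("cis", "trans"):
            raise ValidationError(f"effect kind must be cis or trans, got {self.kind!r}")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the cohort the pipeline targets: 154 genotyped donors
    (129 after QC), MAF spectrum reaching below the 0.15 analysis cutoff,
    log2-scale noise of SD 1, and planted betas within the observed
    magnitude range 0.2-2.0 per minor-allele copy.
    """

    n_samples: int = 154
    n_snps: int = 6000
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.8
    n_probes: int = 400
    planted_effects: list = field(default_factory=list)
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.3, "center": 0.3}
    )
    noise_sd: float = 1.0
    n_y_probes: int = 10
    seed: int = 0
    # generator internals (not part of the scan contract)
    n_chromosomes: int = 4
    snp_spacing: tuple = (2000, 8000)  # bp between adjacent SNPs
    baseline_range: tuple = (6.0, 10.0)  # log2 baseline of expressed probes
    frac_unexpressed: float = 0.15  # probes whose baseline sits below background
    unexpressed_level: tuple = (4.0, 0.3)  # mean, sd of background-level baselines
    frac_contains_snp: float = 0.05
    frac_ambiguous: float = 0.05
    y_female_level: tuple = (4.2, 0.3)  # mean, sd of Y-probe signal in females

    def validate(self) -> None:
        for name in ("n_samples", "n_snps", "ld_block_size", "n_probes", "n_chromosomes"):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be a positive count")
        if self.n_y_probes < 0:
            raise ValidationError("n_y_probes must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_decay < 1):
            raise ValidationError("ld_decay must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def simulate_genotypes(cfg: SimulationConfig, snp_mafs=None):
    """Draw HWE genotypes with block LD.

    Parameters
    ----------
    cfg : SimulationConfig
    snp_mafs : optional array of per-SNP allele frequencies.  When given,
        SNPs are drawn independently (no LD copying, which would require a
        shared within-block frequency); a frequency of 0 yields an all-zero
        dosage column.  Used for targeted tests.

    Returns
    -------
    GenotypeMatrix with positions strictly increasing per chromosome.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 0)
    n, m = cfg.n_samples, cfg.n_snps
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]

    dosage = np.empty((n, m), dtype=float)
    mafs = np.empty(m)

    if snp_mafs is not None:
        snp_mafs = np.asarray(snp_mafs, dtype=float)
        if snp_mafs.shape != (m,):
            raise ValidationError("snp_mafs must have length n_snps")
        if (snp_mafs < 0).any() or (snp_mafs > 0.5).any():
            raise ValidationError("explicit SNP MAFs must lie in [0, 0.5]")
        mafs[:] = snp_mafs
        dosage[:] = rng.binomial(1, snp_mafs, size=(n, m)) + rng.binomial(
            1, snp_mafs, size=(n, m)
        )
    else:
        lo, hi = cfg.maf_range
        for start in range(0, m, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, m)
            width = stop - start
            maf = rng.uniform(lo, hi)
            mafs[start:stop] = maf
            h1 = np.empty((n, width))
            h2 = np.empty((n, width))
            h1[:, 0] = rng.binomial(1, maf, size=n)
            h2[:, 0] = rng.binomial(1, maf, size=n)
            for j in range(1, width):
                for h in (h1, h2):
                    copy = rng.random(n) < cfg.ld_decay
                    fresh = rng.binomial(1, maf, size=n)
                    h[:, j] = np.where(copy, h[:, j - 1], fresh)
            dosage[:, start:stop] = h1 + h2

    # positions: blocks assigned to chromosomes round-robin, strictly
    # increasing 1-based coordinates within each chromosome
    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    cursor = {c: 0 for c in range(1, cfg.n_chromosomes + 1)}
    block_idx = 0
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        c = (block_idx % cfg.n_chromosomes) + 1
        for j in range(start, stop):
            cursor[c] += int(rng.integers(cfg.snp_spacing[0], cfg.snp_spacing[1]))
            chroms[j] = str(c)
            pos[j] = cursor[c]
        block_idx += 1

    alleles = np.array(["A", "C", "G", "T"])
    minor = rng.integers(0, 4, size=m)
    major = (minor + 1 + rng.integers(0, 3, size=m)) % 4

    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "minor_allele": alleles[minor],
            "major_allele": alleles[major],
            "maf": mafs,
            "imputation_rsq": np.nan,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    dos = pd.DataFrame(dosage, index=pd.Index(sample_ids, name="sample"), columns=snps.index)
    return GenotypeMatrix(dosage=dos, snps=snps)


def make_probe_annotation(cfg: SimulationConfig, snp_anno: pd.DataFrame | None = None):
    """Build a probe annotation spanning the simulated chromosomes.

    Genes are placed on the same coordinate span as the SNPs (so cis windows
    are populated), plus ``n_y_probes`` probes on chromosome Y.  The TSS
    equals gene_start on the + strand and gene_end on the - strand.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    records = []
    n_auto = cfg.n_probes
    # coordinate span per chromosome, matching simulate_genotypes
    mean_spacing = (cfg.snp_spacing[0] + cfg.snp_spacing[1]) / 2
    span = int(cfg.n_snps / cfg.n_chromosomes * mean_spacing)
    per_chrom = int(np.ceil(n_auto / cfg.n_chromosomes))
    k = 0
    for c in range(1, cfg.n_chromosomes + 1):
        n_here = min(per_chrom, n_auto - k)
        if n_here <= 0:
            break
        starts = np.sort(rng.integers(1, max(span, 2), size=n_here))
        for s in starts:
            k += 1
            length = int(rng.integers(5_000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gs, ge = int(s), int(s) + length
            records.append(
                {
                    "probe": f"probe{k:05d}",
                    "gene": f"GENE{k:05d}",
                    "chrom": str(c),
                    "strand": strand,
                    "tss": gs if strand == "+" else ge,
                    "gene_start": gs,
                    "gene_end": ge,
                }
            )
    for y in range(cfg.n_y_probes):
        k += 1
        gs = 1_000_000 + y * 100_000
        ge = gs + int(rng.integers(5_000, 50_000))
        records.append(
            {
                "probe": f"probe{k:05d}",
                "gene": f"YGENE{y + 1:03d}",
                "chrom": "Y",
                "strand": "+",
                "tss": gs,
                "gene_start": gs,
                "gene_end": ge,
            }
        )
    probes = pd.DataFrame(records).set_index("probe")
    n_total = len(probes)
    autosomal = probes["chrom"] != "Y"
    probes["contains_snp"] = autosomal & (rng.random(n_total) < cfg.frac_contains_snp)
    probes["ambiguous_mapping"] = autosomal & (rng.random(n_total) < cfg.frac_ambiguous)
    return probes


def make_covariates(cfg: SimulationConfig) -> pd.DataFrame:
    """Donor covariates: age ~ 41 +/- 14 years, sex ~ 74M/55F, four centers."""
    cfg.validate()
    rng = _rng(cfg.seed, 2)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    age = np.clip(np.round(rng.normal(41, 14, size=n)), 18, 75)
    sex = np.where(rng.random(n) < 74 / 129, "M", "F")
    w = np.asarray(CENTER_WEIGHTS, dtype=float)
    center = rng.choice(CENTERS, size=n, p=w / w.sum())
    return pd.DataFrame(
        {"age": age, "sex": sex, "center": center},
        index=pd.Index(sample_ids, name="sample"),
    )


def plant_effects(
    snps: pd.DataFrame,
    probes: pd.DataFrame,
    n_cis: int,
    n_trans: int = 0,
    beta_range: tuple = (0.2, 2.0),
    cis_window: int = 1_000_000,
    seed: int = 0,
) -> list:
    """Choose SNP-probe pairs and effect sizes for planting.

    Cis pairs are drawn with the SNP within ``cis_window`` of the probe TSS
    on the same chromosome; trans pairs violate that.  Betas are uniform in
    magnitude over ``beta_range`` with random sign.  At most one effect per
    probe.
    """
    rng = _rng(seed, 3)
    auto = probes[probes["chrom"] != "Y"]
    effects: list[PlantedEffect] = []
    used_probes: set = set()
    probe_order = auto.index.to_numpy().copy()  # copy: shuffle must not touch the index
    rng.shuffle(probe_order)
    snp_chrom = snps["chrom"].to_numpy()
    snp_pos = snps["pos"].to_numpy()

    def draw_beta():
        return float(rng.uniform(*beta_range) * rng.choice([-1.0, 1.0]))

    for pid in probe_order:
        if len(effects) >= n_cis:
            break
        row = auto.loc[pid]
        mask = (snp_chrom == row["chrom"]) & (np.abs(snp_pos - row["tss"]) <= cis_window)
        cands = snps.index[mask]
        if len(cands) == 0 or pid in used_probes:
            continue
        effects.append(PlantedEffect(str(rng.choice(cands)), pid, draw_beta(), "cis"))
        used_probes.add(pid)
    if len(effects) < n_cis:
        raise ValidationError("not enough cis SNP-probe pairs to plant the requested effects")
    n_found = 0
    for pid in probe_order:
        if n_found >= n_trans:
            break
        if pid in used_probes:
            continue
        row = auto.loc[pid]
        mask = (snp_chrom != row["chrom"]) | (np.abs(snp_pos - row["tss"]) > cis_window)
        cands = snps.index[mask]
        if len(cands) == 0:
            continue
        effects.append(PlantedEffect(str(rng.choice(cands)), pid, draw_beta(), "trans"))
        used_probes.add(pid)
        n_found += 1
    return effects


def simulate_expression(
    G: GenotypeMatrix,
    probes: pd.DataFrame,
    covars: pd.DataFrame,
    cfg: SimulationConfig,
) -> ExpressionMatrix:
    """Generate log2 expression: baseline + planted genetics + covariates + noise.

    Y-chromosome probes get background-level values in females (no Y
    transcription) and ordinary baselines in males; a ``frac_unexpressed``
    share of autosomal probes sits at background level so the detection
    filter has something to remove.
    """
    cfg.validate()
    if not G.sample_ids.equals(covars.index):
        raise ValidationError("genotype and covariate sample ids differ")
    rng = _rng(cfg.seed, 4)
    n = G.n_samples
    p = len(probes)
    probe_ids = probes.index

    baseline = rng.uniform(*cfg.baseline_range, size=p)
    unexpressed = (probes["chrom"] != "Y").to_numpy() & (
        rng.random(p) < cfg.frac_unexpressed
    )
    baseline[unexpressed] = rng.normal(*cfg.unexpressed_level, size=int(unexpressed.sum()))

    E = np.tile(baseline, (n, 1)) + rng.normal(0.0, cfg.noise_sd, size=(n, p))

    # covariate structure: per-probe random slopes scaled by the configured SDs
    eff = cfg.covariate_effects or {}
    age = covars["age"].to_numpy(dtype=float)
    male = (covars["sex"].astype(str).str.upper().str.startswith("M")).to_numpy()
    if eff.get("age"):
        coef = rng.normal(0.0, eff["age"], size=p)
        E += np.outer(age - age.mean(), coef)
    if eff.get("sex"):
        coef = rng.normal(0.0, eff["sex"], size=p)
        E += np.outer(male.astype(float), coef)
    if eff.get("center"):
        for level in pd.unique(covars["center"]):
            coef = rng.normal(0.0, eff["center"], size=p)
            E += np.outer((covars["center"] == level).to_numpy(float), coef)

    # planted additive genetic effects
    probe_loc = {pid: i for i, pid in enumerate(probe_ids)}
    for effect in cfg.planted_effects:
        if effect.snp_id not in G.snp_ids:
            raise ValidationError(f"planted effect references unknown SNP {effect.snp_id!r}")
        if effect.probe_id not in probe_loc:
            raise ValidationError(f"planted effect references unknown probe {effect.probe_id!r}")
        snp = G.snps.loc[effect.snp_id]
        probe = probes.loc[effect.probe_id]
        is_cis = (str(snp["chrom"]) == str(probe["chrom"])) and (
            abs(int(snp["pos"]) - int(probe["tss"])) <= 1_000_000
        )
        if effect.kind == "cis" and not is_cis:
            raise ValidationError(
                f"effect {effect.snp_id}->{effect.probe_id} declared cis but lies outside 1 Mb"
            )
        if effect.kind == "trans" and is_cis:
            raise ValidationError(
                f"effect {effect.snp_id}->{effect.probe_id} declared trans but lies within 1 Mb"
            )
        d = G.dosage[effect.snp_id].to_numpy(dtype=float)
        d = np.where(np.isnan(d), np.nanmean(d), d)
        E[:, probe_loc[effect.probe_id]] += effect.beta * d

    # Y probes: background in females
    y_idx = np.where((probes["chrom"] == "Y").to_numpy())[0]
    female = ~male
    if len(y_idx) and female.any():
        mu, sd = cfg.y_female_level
        E[np.ix_(female, y_idx)] = rng.normal(mu, sd, size=(int(female.sum()), len(y_idx)))

    values = pd.DataFrame(E, index=G.sample_ids.copy(), columns=probe_ids.copy())
    return ExpressionMatrix(values=values, probes=probes)


@dataclass
class DefectSpec:
    """How many samples to corrupt, per QC defect class."""

    n_low_call: int = 0
    low_call_frac: float = 0.10  # fraction of genotypes masked
    n_duplicates: int = 0
    dup_flip_frac: float = 0.002  # genotype discordance within a duplicate pair
    n_het_excess: int = 0
    n_het_deficit: int = 0
    het_frac: float = 0.9  # fraction of SNPs forced het / hom
    n_stratified: int = 0
    strat_shift: float = 0.2  # allele-frequency shift of the outlier subgroup
    strat_snp_frac: float = 0.3  # fraction of SNPs shifted
    n_expression_outliers: int = 0

    def total(self) -> int:
        return (
            self.n_low_call
            + 2 * self.n_duplicates  # source + copy are both committed
            + self.n_het_excess
            + self.n_het_deficit
            + self.n_stratified
            + self.n_expression_outliers
        )


def inject_qc_defects(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covars: pd.DataFrame,
    spec: DefectSpec,
    seed: int = 0,
):
    """Corrupt disjoint samples per ``spec`` and return ground-truth labels.

    Returns (G', E', covars, labels) where ``labels`` is a DataFrame with
    columns ``sample, defect`` (one row per defective sample; the retained
    member of a duplicate pair is labelled ``duplicate_source``).
    """
    rng = _rng(seed, 5)
    n = G.n_samples
    if spec.total() > n:
        raise ValidationError("defect assignments exceed the number of samples")
    order = G.sample_ids.to_numpy().copy()
    rng.shuffle(order)
    it = iter(order)

    def take(k):
        return [next(it) for _ in range(k)]

    dosage = G.dosage.copy()
    values = E.values.copy()
    labels = []
    mafs = G.snps["maf"].to_numpy(dtype=float)
    m = G.n_snps

    for s in take(spec.n_low_call):
        mask = rng.random(m) < spec.low_call_frac
        dosage.loc[s, mask] = np.nan
        labels.append((s, "low_call_rate"))

    for _ in range(spec.n_duplicates):
        src, dst = take(2)
        row = dosage.loc[src].to_numpy(dtype=float).copy()
        flip = rng.random(m) < spec.dup_flip_frac
        row[flip] = rng.binomial(2, mafs[flip]).astype(float)
        dosage.loc[dst] = row
        labels.append((src, "duplicate_source"))
        labels.append((dst, "duplicate"))

    for s in take(spec.n_het_excess):
        mask = rng.random(m) < spec.het_frac
        dosage.loc[s, mask] = 1.0
        labels.append((s, "het_excess"))

    for s in take(spec.n_het_deficit):
        mask = rng.random(m) < spec.het_frac
        hom = 2.0 * rng.binomial(1, mafs[np.where(mask)[0]]).astype(float)
        dosage.loc[s, mask] = hom
        labels.append((s, "het_deficit"))

    strat_samples = take(spec.n_stratified)
    if strat_samples:
        snp_mask = rng.random(m) < spec.strat_snp_frac
        shifted = np.clip(mafs[snp_mask] + spec.strat_shift, 0.0, 0.99)
        for s in strat_samples:
            dosage.loc[s, snp_mask] = rng.binomial(2, shifted).astype(float)
            labels.append((s, "stratified"))

    for s in take(spec.n_expression_outliers):
        vals = values.to_numpy()
        values.loc[s] = rng.normal(np.nanmean(vals), np.nanstd(vals), size=values.shape[1])
        labels.append((s, "expression_outlier"))

    labels_df = pd.DataFrame(labels, columns=["sample", "defect"])
    G2 = GenotypeMatrix(dosage=dosage, snps=G.snps.copy())
    E2 = ExpressionMatrix(values=values, probes=E.probes.copy())
    return G2, E2, covars.copy(), labels_df


def simulate_cohort(cfg: SimulationConfig, defects: DefectSpec | None = None):
    """Convenience wrapper: genotypes + annotation + covariates + expression.

    Returns (G, E, covars, labels); ``labels`` is empty when no defects are
    requested.
    """
    G = simulate_genotypes(cfg)
    probes = make_probe_annotation(cfg, G.snps)
    covars = make_covariates(cfg)
    E = simulate_expression(G, probes, covars, cfg)
    if defects is None:
        labels = pd.DataFrame(columns=["sample", "defect"])
        return G, E, covars, labels
    return inject_qc_defects(G, E, covars, defects, seed=cfg.seed)


GWAS_TRAITS = (
    "sudden cardiac death", "atrial fibrillation", "heart rate",
    "PR duration", "QRS duration", "QTc duration",
)


def make_gwas_list(
    G: GenotypeMatrix,
    planted: pd.DataFrame,
    n_true: int = 8,
    n_random: int = 8,
    min_maf: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic trait-associated SNP list for the overlap stage.

    Mixes planted eQTL SNPs (true positives) with random non-eQTL SNPs,
    all with MAF >= ``min_maf``; traits cycle through the six cardiac
    categories and source p-values sit at genome-wide significance.
    """
    rng = _rng(seed, 8)
    maf = G.empirical_maf()
    eligible = maf.index[maf >= min_maf]
    true_pool = [s for s in planted["snp"] if s in set(eligible)]
    true_snps = true_pool[:n_true]
    rest = [s for s in eligible if s not in set(true_snps)]
    rand_snps = list(rng.choice(rest, size=min(n_random, len(rest)), replace=False))
    rows = []
    for i, s in enumerate(true_snps + rand_snps):
        a = G.snps.loc[s]
        rows.append(
            {
                "snp": s,
                "chrom": a["chrom"],
                "pos": int(a["pos"]),
                "trait": GWAS_TRAITS[i % len(GWAS_TRAITS)],
                "reported_gene": "-",
                "p_gwas": float(10 ** rng.uniform(-12, np.log10(5e-8))),
            }
        )
    return pd.DataFrame(rows)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["planted_effects"] = [dataclasses.asdict(e) for e in cfg.planted_effects]
    return d
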