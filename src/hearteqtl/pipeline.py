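"""Stage orchestration: simulate -> QC -> scan -> GWAS overlap -> power.

Each stage reads/writes plain TSV files in a working directory, echoes the
full configuration next to its outputs and appends filter-cascade counts to
a run log, so a pipeline run is reproducible from the directory contents
alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .datatypes import ValidationError
from .expression_qc import detection_threshold, filter_probes, normalize
from .genotype_qc import run_genotype_qc
from .gwas import (
    annotate_tss_distance,
    enrichment,
    matched_random_sets,
    nominal_snp_indicator,
    prune_gwas_loci,
    test_gwas_snps,
)
from .mapping import ScanConfig, ld_prune, run_scan
from .power import PowerGrid, simulate_power
from .simulate import (
    DefectSpec,
    SimulationConfig,
    config_to_dict,
    plant_effects,
    simulate_cohort,
    simulate_genotypes,
    make_probe_annotation,
)

log = logging.getLogger("hearteqtl")

#: study-condition defaults: a 154-donor genotyped cohort carrying 13
#: stratified outliers and 12 other defective samples (129 clean), 20 cis +
#: 1 trans planted effect with |beta| in 0.2-2.0
DEFAULT_CONFIG = {
    "seed": 0,
    "simulation": {
        "n_samples": 154,
        "n_snps": 6000,
        "maf_range": [0.05, 0.5],
        "ld_block_size": 10,
        "ld_decay": 0.8,
        "n_probes": 400,
        "noise_sd": 1.0,
        "n_y_probes": 10,
        "n_chromosomes": 4,
        "n_cis_effects": 20,
        "n_trans_effects": 1,
        "beta_range": [0.2, 2.0],
    },
    "defects": {
        "n_low_call": 4,
        "n_duplicates": 4,
        "n_het_excess": 2,
        "n_het_deficit": 2,
        "n_stratified": 13,
    },
    "expression_qc": {"cut_scale": 1.3, "min_cluster_frac": 0.25},
    "genotype_qc": {
        "min_call_rate": 0.95,
        "max_ibs": 0.95,
        "het_fdr": 0.01,
        "min_cluster_frac": 0.25,
        "strat_cut_scale": 1.05,
        "min_maf": 0.15,
        "rsq_cutoff": 0.30,
    },
    "scan": {
        "cis_window": 1_000_000,
        "cis_fdr": 0.05,
        "trans_p_floor": 5e-8,
        "trans_fdr": 0.05,
        "ld_r2": 0.6,
    },
    "gwas": {"n_sets": 10_000, "nominal_p": 0.05, "count_level": "locus"},
    "power": {
        "maf_levels": [0.05, 0.10, 0.15, 0.20, 0.30, 0.40],
        "n": 129,
        "n_eqtls": 1000,
        "noise_sd": 1.0,
        "fdr": 0.05,
        "reps": 2,
    },
}


def merge_config(user: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _setup_dir(outdir, cfg: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.dump_config(cfg, outdir / "config_used.yaml")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "run.log").resolve()
        for h in log.handlers
    ):
        log.addHandler(handler)
    log.setLevel(logging.INFO)
    return outdir


def make_simulation_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg["simulation"])
    n_cis = sim.pop("n_cis_effects", 0)
    n_trans = sim.pop("n_trans_effects", 0)
    beta_range = tuple(sim.pop("beta_range", (0.2, 2.0)))
    sim["maf_range"] = tuple(sim["maf_range"])
    scfg = SimulationConfig(seed=cfg["seed"], **sim)
    if n_cis or n_trans:
        G0 = simulate_genotypes(scfg)
        probes = make_probe_annotation(scfg)
        scfg.planted_effects = plant_effects(
            G0.snps, probes, n_cis, n_trans, beta_range, seed=cfg["seed"]
        )
    return scfg


def stage_simulate(cfg: dict, outdir):
    """Generate the synthetic cohort (with QC defects) and write its files."""
    outdir = _setup_dir(outdir, cfg)
    scfg = make_simulation_config(cfg)
    defects = DefectSpec(**cfg["defects"])
    G, E, covars, labels = simulate_cohort(scfg, defects)
    io.write_genotypes_tsv(G, outdir / "genotypes.tsv", outdir / "snp_annotation.tsv")
    io.write_expression_tsv(E, outdir / "expression.tsv", outdir / "probe_annotation.tsv")
    io.write_covariates_tsv(covars, outdir / "covariates.tsv")
    labels.to_csv(outdir / "defect_labels.tsv", sep="\t", index=False)
    planted = pd.DataFrame(
        [
            {"snp": e.snp_id, "probe": e.probe_id, "beta": e.beta, "kind": e.kind}
            for e in scfg.planted_effects
        ]
    )
    planted.to_csv(outdir / "planted_effects.tsv", sep="\t", index=False)
    log.info(
        "simulated %d samples, %d SNPs, %d probes; %d defective samples; %d planted effects",
        G.n_samples, G.n_snps, len(E.probe_ids), labels["sample"].nunique(), len(planted),
    )
    return G, E, covars, labels


def stage_expression_qc(cfg: dict, workdir):
    """Normalize expression, form the detection threshold, filter probes."""
    workdir = Path(workdir)
    E = io.read_expression_tsv(workdir / "expression.tsv", workdir / "probe_annotation.tsv")
    covars = io.read_covariates_tsv(workdir / "covariates.tsv")
    E = normalize(E)
    threshold = detection_threshold(E, covars["sex"])
    retained, counts = filter_probes(E, threshold)
    E_kept = E.subset(probes=retained)
    io.write_expression_tsv(
        E_kept, workdir / "expression_qc.tsv", workdir / "probe_annotation_qc.tsv"
    )
    pd.DataFrame([counts]).to_csv(workdir / "probe_exclusions.tsv", sep="\t", index=False)
    log.info(
        "expression QC: detection threshold %.3f; probes %d -> %d "
        "(contains_snp %d, ambiguous %d, below threshold %d)",
        threshold, len(E.probe_ids), counts["retained"], counts["contains_snp"],
        counts["ambiguous_mapping"], counts["below_threshold"],
    )
    return E_kept, threshold, counts


def stage_genotype_qc(cfg: dict, workdir):
    """Run the genotype QC cascade on the simulated files."""
    workdir = Path(workdir)
    G = io.read_genotypes_tsv(workdir / "genotypes.tsv", workdir / "snp_annotation.tsv")
    clean, report = run_genotype_qc(G, **cfg["genotype_qc"])
    io.write_genotypes_tsv(
        clean, workdir / "genotypes_qc.tsv", workdir / "snp_annotation_qc.tsv"
    )
    report.summary().to_csv(workdir / "qc_removals.tsv", sep="\t", index=False)
    report.sample_stats.to_csv(workdir / "qc_sample_stats.tsv", sep="\t")
    reasons = pd.Series(list(report.removed_samples.values())).value_counts().to_dict()
    log.info(
        "genotype QC: samples %d -> %d (removed by reason: %s); SNPs %d -> %d",
        G.n_samples, len(report.retained_samples), reasons, G.n_snps,
        len(report.retained_snps),
    )
    return clean, report


def stage_scan(cfg: dict, workdir):
    """Genome-wide eQTL scan on QC'd inputs, plus LD pruning."""
    workdir = Path(workdir)
    G = io.read_genotypes_tsv(
        workdir / "genotypes_qc.tsv", workdir / "snp_annotation_qc.tsv"
    )
    E = io.read_expression_tsv(
        workdir / "expression_qc.tsv", workdir / "probe_annotation_qc.tsv"
    )
    covars = io.read_covariates_tsv(workdir / "covariates.tsv")
    G, E, covars = io.intersect_samples(G, E, covars)
    scan_cfg = ScanConfig(**cfg["scan"])
    result = run_scan(G, E, covars, scan_cfg)
    result.records.to_csv(workdir / "eqtl_records.tsv", sep="\t", index=False)
    clusters = ld_prune(result.records, G, scan_cfg.ld_r2)
    cluster_rows = []
    for c in clusters:
        for _, rec in c.representative_records().iterrows():
            cluster_rows.append(
                {
                    "cluster": c.cluster_id,
                    "top_snp": c.top_snp,
                    "n_snps": len(c.snp_ids),
                    **rec[
                        ["snp", "probe", "gene", "chrom", "pos", "p", "beta", "maf",
                         "minor_allele", "major_allele", "distance", "position_label",
                         "relation"]
                    ].to_dict(),
                }
            )
    pd.DataFrame(cluster_rows).to_csv(workdir / "eqtl_clusters.tsv", sep="\t", index=False)
    n_transcripts = result.records["probe"].nunique() if len(result.records) else 0
    log.info(
        "scan: %d tests (%d cis, %d trans); %d significant records; cis window %d bp "
        "(boundary inclusive); %d LD clusters over %d transcripts; cis p threshold %.3g",
        result.n_tests, result.n_cis_tests, result.n_trans_tests, len(result.records),
        scan_cfg.cis_window, len(clusters), n_transcripts, result.cis_p_threshold,
    )
    return result, clusters


def stage_overlap(cfg: dict, workdir, gwas_path=None):
    """GWAS SNP look-up and matched-resampling enrichment."""
    workdir = Path(workdir)
    gwas_path = Path(gwas_path) if gwas_path else workdir / "gwas_snps.tsv"
    if not gwas_path.exists() or gwas_path.stat().st_size == 0:
        log.info("no GWAS list found at %s; overlap stage skipped", gwas_path)
        return None
    gwas = io.read_gwas_tsv(gwas_path)
    if len(gwas) == 0:
        log.info("empty GWAS list; overlap stage skipped")
        return None
    G = io.read_genotypes_tsv(
        workdir / "genotypes_qc.tsv", workdir / "snp_annotation_qc.tsv"
    )
    E = io.read_expression_tsv(
        workdir / "expression_qc.tsv", workdir / "probe_annotation_qc.tsv"
    )
    covars = io.read_covariates_tsv(workdir / "covariates.tsv")
    G, E, covars = io.intersect_samples(G, E, covars)
    gcfg = cfg["gwas"]
    scan_cfg = ScanConfig(**cfg["scan"])

    loci = prune_gwas_loci(gwas, G, r2=scan_cfg.ld_r2)
    table, nominal, Q, threshold = test_gwas_snps(
        loci, G, E, covars, scan_cfg,
        nominal_p=gcfg["nominal_p"], count_level=gcfg["count_level"],
    )
    table.to_csv(workdir / "gwas_eqtl_table.tsv", sep="\t", index=False)
    nominal.to_csv(workdir / "gwas_eqtl_nominal.tsv", sep="\t", index=False)

    pool = G.snps.copy()
    pool["maf"] = G.empirical_maf()
    pool["tss_dist"] = annotate_tss_distance(pool, E.probes)
    lead_snps = [L["lead"] for L in loci if L["lead"] in G.snp_ids]
    flag = nominal_snp_indicator(G, E, covars, gcfg["nominal_p"])
    sets = matched_random_sets(pool, lead_snps, gcfg["n_sets"], seed=cfg["seed"])
    Q_i = np.array([int(flag[s].sum()) for s in sets])
    result = enrichment(Q, Q_i)
    summary = pd.DataFrame(
        [
            {
                "n_gwas_snps": gwas["snp"].nunique(),
                "n_loci": len(loci),
                "bonferroni_threshold": threshold,
                "Q": result.Q,
                "fold_enrichment": result.fold,
                "p_empirical": result.p_emp,
                "n_sets": result.n_sets,
                "n_zero_null_sets": result.n_substituted,
            }
        ]
    )
    summary.to_csv(workdir / "enrichment_summary.tsv", sep="\t", index=False)
    log.info(
        "overlap: %d GWAS SNPs -> %d loci; Bonferroni threshold %.3g; Q=%d; "
        "fold enrichment %.2f; empirical p %.4f over %d matched sets",
        gwas["snp"].nunique(), len(loci), threshold, result.Q, result.fold,
        result.p_emp, result.n_sets,
    )
    return {"loci": loci, "table": table, "nominal": nominal, "Q": Q,
            "threshold": threshold, "enrichment": result}


def stage_power(cfg: dict, workdir):
    """Power table over the MAF x fold-change grid."""
    workdir = Path(workdir)
    pcfg = dict(cfg["power"])
    pcfg["maf_levels"] = tuple(pcfg["maf_levels"])
    grid = PowerGrid(seed=cfg["seed"], **pcfg)
    table = simulate_power(grid)
    table.to_csv(workdir / "power_table.tsv", sep="\t", index=False)
    log.info("power: %d grid points at n=%d, FDR %.2f", len(table), grid.n, grid.fdr)
    return table


def run_all(cfg: dict, outdir):
    """End-to-end pipeline on the synthetic cohort."""
    cfg = merge_config(cfg)
    outdir = _setup_dir(outdir, cfg)
    stage_simulate(cfg, outdir)
    stage_expression_qc(cfg, outdir)
    stage_genotype_qc(cfg, outdir)
    result, clusters = stage_scan(cfg, outdir)
    overlap = stage_overlap(cfg, outdir)
    power = stage_power(cfg, outdir)
    return {"scan": result, "clusters": clusters, "overlap": overlap, "power": power}
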