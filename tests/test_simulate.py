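import numpy as np
import pandas as pd
import pytest

from hearteqtl.datatypes import ValidationError
from hearteqtl.genotype_qc import ibs_matrix
from hearteqtl.mapping import fit_eqtl, ld_r2
from hearteqtl.simulate import (
    DefectSpec,
    PlantedEffect,
    SimulationConfig,
    inject_qc_defects,
    make_covariates,
    make_gwas_list,
    make_probe_annotation,
    plant_effects,
    simulate_expression,
    simulate_genotypes,
)

from conftest import small_config


def test_invalid_maf_range_rejected():
    with pytest.raises(ValidationError):
        SimulationConfig(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ValidationError):
        SimulationConfig(maf_range=(0.1, 0.6)).validate()


def test_zero_maf_gives_all_zero_dosages():
    cfg = small_config(n_snps=5)
    G = simulate_genotypes(cfg, snp_mafs=[0.0, 0.3, 0.0, 0.2, 0.1])
    assert (G.dosage[G.snp_ids[0]] == 0).all()
    assert (G.dosage[G.snp_ids[2]] == 0).all()


def test_empirical_frequency_matches_target():
    cfg = small_config(n_samples=10_000, n_snps=20)
    G = simulate_genotypes(cfg, snp_mafs=[0.3] * 20)
    freq = G.dosage.to_numpy().mean(axis=0) / 2
    # 3-sigma band of the binomial mean at n=10000
    se = np.sqrt(0.3 * 0.7 / (2 * 10_000))
    assert (np.abs(freq - 0.3) < 3 * se + 1e-9).all()


def test_off_block_independence():
    cfg = small_config(n_samples=10_000, n_snps=40, ld_block_size=10, ld_decay=0.0)
    G = simulate_genotypes(cfg)
    D = G.dosage.to_numpy()
    r2s = [ld_r2(D[:, i], D[:, i + 10]) for i in range(10)]
    assert np.mean(r2s) < 0.01


def test_within_block_ld_present():
    cfg = small_config(n_samples=2_000, n_snps=20, ld_block_size=10, ld_decay=0.8)
    G = simulate_genotypes(cfg)
    D = G.dosage.to_numpy()
    assert ld_r2(D[:, 0], D[:, 1]) > 0.3


def test_positions_strictly_increasing_per_chromosome():
    cfg = small_config()
    G = simulate_genotypes(cfg)
    for _, group in G.snps.groupby("chrom"):
        assert group["pos"].is_monotonic_increasing
        assert group["pos"].diff().dropna().gt(0).all()


def test_genotypes_deterministic_per_seed():
    cfg = small_config()
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    pd.testing.assert_frame_equal(a.dosage, b.dosage)


def test_probe_annotation_conventions():
    cfg = small_config(n_y_probes=5)
    probes = make_probe_annotation(cfg)
    assert (probes["chrom"] == "Y").sum() == 5
    plus = probes[probes["strand"] == "+"]
    minus = probes[probes["strand"] == "-"]
    assert (plus["tss"] == plus["gene_start"]).all()
    assert (minus["tss"] == minus["gene_end"]).all()
    assert (probes["gene_start"] <= probes["gene_end"]).all()


def test_planted_effect_recovered_noiselessly():
    cfg = small_config(noise_sd=1e-12, covariate_effects={})
    G = simulate_genotypes(cfg)
    probes = make_probe_annotation(cfg, G.snps)
    covars = make_covariates(cfg)
    effects = plant_effects(G.snps, probes, n_cis=1, seed=cfg.seed)
    cfg.planted_effects = effects
    E = simulate_expression(G, probes, covars, cfg)
    e = effects[0]
    fit = fit_eqtl(E.values[e.probe_id], G.dosage[e.snp_id])
    assert fit["beta"] == pytest.approx(e.beta, abs=1e-8)


def test_planted_beta_consistent_at_large_n():
    cfg = small_config(n_samples=10_000, n_snps=50, n_probes=10, covariate_effects={})
    G = simulate_genotypes(cfg, snp_mafs=[0.24] * 50)
    probes = make_probe_annotation(cfg, G.snps)
    covars = make_covariates(cfg)
    probe = probes.index[probes["chrom"] != "Y"][0]
    snp = G.snps.index[G.snps["chrom"] == probes.loc[probe, "chrom"]][0]
    cfg.planted_effects = [PlantedEffect(snp, probe, 1.5, "cis")]
    E = simulate_expression(G, probes, covars, cfg)
    fit = fit_eqtl(E.values[probe], G.dosage[snp])
    assert abs(fit["beta"] - 1.5) < 0.05


def test_unknown_planted_id_named_in_error():
    cfg = small_config()
    G = simulate_genotypes(cfg)
    probes = make_probe_annotation(cfg, G.snps)
    covars = make_covariates(cfg)
    cfg.planted_effects = [PlantedEffect("nope", probes.index[0], 1.0, "cis")]
    with pytest.raises(ValidationError, match="nope"):
        simulate_expression(G, probes, covars, cfg)


def test_plant_effects_geometry():
    cfg = small_config(n_probes=60)
    G = simulate_genotypes(cfg)
    probes = make_probe_annotation(cfg, G.snps)
    effects = plant_effects(G.snps, probes, n_cis=5, n_trans=2, seed=3)
    assert len(effects) == 7
    assert len({e.probe_id for e in effects}) == 7  # at most one effect per probe
    for e in effects:
        snp = G.snps.loc[e.snp_id]
        probe = probes.loc[e.probe_id]
        is_cis = str(snp["chrom"]) == str(probe["chrom"]) and abs(
            int(snp["pos"]) - int(probe["tss"])
        ) <= 1_000_000
        assert is_cis == (e.kind == "cis")
        assert 0.2 <= abs(e.beta) <= 2.0


def test_injected_duplicate_has_high_ibs(small_cohort):
    G, E, covars, cfg = small_cohort
    G2, _, _, labels = inject_qc_defects(G, E, covars, DefectSpec(n_duplicates=1), seed=7)
    src = labels.loc[labels["defect"] == "duplicate_source", "sample"].iloc[0]
    dst = labels.loc[labels["defect"] == "duplicate", "sample"].iloc[0]
    assert ibs_matrix(G2).loc[src, dst] > 0.99


def test_injected_low_call_rate(small_cohort):
    G, E, covars, cfg = small_cohort
    spec = DefectSpec(n_low_call=1, low_call_frac=0.10)
    G2, _, _, labels = inject_qc_defects(G, E, covars, spec, seed=7)
    s = labels.loc[labels["defect"] == "low_call_rate", "sample"].iloc[0]
    assert G2.call_rate()[s] < 0.95


def test_defect_overflow_rejected(small_cohort):
    G, E, covars, cfg = small_cohort
    with pytest.raises(ValidationError):
        inject_qc_defects(G, E, covars, DefectSpec(n_low_call=G.n_samples + 1), seed=0)


def test_make_gwas_list_contract(small_cohort):
    G, E, covars, cfg = small_cohort
    planted = pd.DataFrame({"snp": [G.snp_ids[0]], "probe": ["x"], "beta": [1.0],
                            "kind": ["cis"]})
    gwas = make_gwas_list(G, planted, n_true=1, n_random=5, seed=2)
    assert (gwas["p_gwas"] <= 5e-8).all()
    maf = G.empirical_maf()
    assert (maf[gwas["snp"]].to_numpy() >= 0.15).all()
    assert gwas["snp"].is_unique
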