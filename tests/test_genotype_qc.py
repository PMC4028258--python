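import itertools

import numpy as np
import pandas as pd
import pytest

from hearteqtl.datatypes import ValidationError
from hearteqtl.genotype_qc import (
    call_rate_filter,
    expected_hom_count,
    hard_calls,
    heterozygosity,
    heterozygosity_outliers,
    ibs_matrix,
    ibs_relatedness_filter,
    imputation_rsq_filter,
    maf_filter,
    robust_z,
    run_genotype_qc,
    stratification_outliers,
)
from hearteqtl.simulate import DefectSpec, inject_qc_defects

from conftest import toy_genotypes


def test_hard_calls_uncertain_bands():
    d = np.array([0.0, 0.2, 0.5, 0.8, 1.0, 1.4, 1.8, 2.0, np.nan])
    out = hard_calls(d)
    expected = np.array([0.0, 0.0, np.nan, 1.0, 1.0, np.nan, 2.0, 2.0, np.nan])
    np.testing.assert_array_equal(out, expected)


def test_call_rate_boundary():
    # 100 SNPs: sample A has 94 called, B exactly 95, C all called
    d = np.ones((3, 100))
    d[0, :6] = np.nan
    d[1, :5] = np.nan
    G = toy_genotypes(d)
    assert call_rate_filter(G, 0.95) == ["S0"]


def test_heterozygosity_counts_het_fraction():
    d = np.array([[1.0, 1.0, 0.0, 2.0], [0.0, 0.0, 0.0, 0.0]])
    het = heterozygosity(toy_genotypes(d))
    assert het["S0"] == 0.5
    assert het["S1"] == 0.0


def test_robust_z_matches_brute_force():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    np.testing.assert_allclose(robust_z(x), (x - med) / mad, atol=1e-12)


def test_het_outlier_flagged():
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.3, size=(40, 200)).astype(float)
    d[0] = 0.0  # heterozygosity 0 among HWE samples
    flagged = heterozygosity_outliers(toy_genotypes(d), fdr=0.01)
    assert "S0" in flagged


def test_het_no_outliers_when_identical():
    d = np.tile(np.array([1.0, 0.0, 2.0, 1.0] * 25), (12, 1))
    with pytest.warns(UserWarning):  # MAD = 0 -> mean/SD fallback
        flagged = heterozygosity_outliers(toy_genotypes(d), fdr=0.01)
    assert flagged == []


def test_ibs_definition_extremes():
    d = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 2.0], [0.0, 2.0, 0.0]])
    ibs = ibs_matrix(toy_genotypes(d))
    assert ibs.loc["S0", "S1"] == 0.0  # opposite homozygotes at every SNP
    assert ibs.loc["S0", "S2"] == 1.0  # identical


def test_ibs_matches_genotype_pair_enumeration():
    # expected IBS of two independent HWE samples at MAF q equals the closed
    # form over the 9 genotype pairs
    q = 0.3
    probs = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q**2}
    expected = sum(
        probs[a] * probs[b] * (1 - abs(a - b) / 2)
        for a, b in itertools.product(probs, repeat=2)
    )
    rng = np.random.default_rng(3)
    d = rng.binomial(2, q, size=(2, 200_000)).astype(float)
    ibs = ibs_matrix(toy_genotypes(d))
    assert ibs.loc["S0", "S1"] == pytest.approx(expected, abs=0.005)


def test_ibs_filter_drops_lower_call_rate_member():
    rng = np.random.default_rng(4)
    base = rng.binomial(2, 0.4, size=100).astype(float)
    d = np.vstack([base, base, rng.binomial(2, 0.4, size=100)]).astype(float)
    d[0, :10] = np.nan  # S0 has the lower call rate of the duplicate pair
    removed = ibs_relatedness_filter(toy_genotypes(d), 0.95)
    assert removed == ["S0"]


@pytest.fixture(scope="module")
def genome_cohort():
    # Manhattan-distance separation of a frequency-shifted subgroup needs a
    # genome-sized SNP panel (signal grows with the SNP count), so these
    # tests use a larger cohort than the small shared fixture
    from conftest import small_config
    from hearteqtl.simulate import (
        make_covariates,
        make_probe_annotation,
        simulate_expression,
        simulate_genotypes,
    )

    cfg = small_config(n_samples=100, n_snps=4000, seed=9)
    G = simulate_genotypes(cfg)
    probes = make_probe_annotation(cfg, G.snps)
    covars = make_covariates(cfg)
    E = simulate_expression(G, probes, covars, cfg)
    return G, E, covars


def test_stratification_flags_shifted_subgroup(genome_cohort):
    G, E, covars = genome_cohort
    G2, _, _, labels = inject_qc_defects(
        G, E, covars, DefectSpec(n_stratified=10), seed=9
    )
    flagged, pcs = stratification_outliers(G2, cut_scale=1.05)
    truth = set(labels.loc[labels["defect"] == "stratified", "sample"])
    assert set(flagged) == truth
    # the subgroup separates on the first principal component
    inside = pcs.loc[sorted(truth), "PC1"].mean()
    outside = pcs.drop(index=truth)["PC1"].mean()
    assert abs(inside - outside) > 3 * pcs.drop(index=truth)["PC1"].std()


def test_stratification_homogeneous_no_flags(genome_cohort):
    G, _, _ = genome_cohort
    flagged, _ = stratification_outliers(G, cut_scale=1.05)
    assert flagged == []
    flagged2, _ = stratification_outliers(G, cut_scale=1.05)
    assert flagged == flagged2  # deterministic


def test_maf_filter_boundary():
    n = 1000
    d = np.zeros((n, 3))
    d[:150, 0] = 2.0  # maf exactly 0.15
    d[:149, 1] = 2.0  # maf 0.149
    G = toy_genotypes(d)
    kept = maf_filter(G, 0.15)
    assert kept == ["v0"]  # 0.149 removed, monomorphic removed


def test_expected_hom_count():
    assert expected_hom_count(129, 0.15) == pytest.approx(2.9025)
    assert round(expected_hom_count(129, 0.15)) == 3
    assert expected_hom_count(77, 0.0) == 0.0
    assert expected_hom_count(100, 0.5) == 25.0
    with pytest.raises(ValidationError):
        expected_hom_count(100, 0.6)


def test_imputation_rsq_filter_enumeration():
    d = np.ones((4, 5))
    G = toy_genotypes(d, rsq=[0.29, 0.30, np.nan, 0.95, 0.0])
    kept = imputation_rsq_filter(G.snps, 0.30)
    assert kept == ["v1", "v2", "v3"]
    bad = toy_genotypes(np.ones((2, 1)), rsq=[1.5])
    with pytest.raises(ValidationError):
        imputation_rsq_filter(bad.snps)


def test_full_cascade_on_injected_defects(genome_cohort):
    G, E, covars = genome_cohort
    spec = DefectSpec(n_low_call=2, n_duplicates=1, n_het_excess=1, n_stratified=8)
    G2, _, _, labels = inject_qc_defects(G, E, covars, spec, seed=13)
    clean, report = run_genotype_qc(G2)
    truth = labels.set_index("sample")["defect"]
    pair = set(truth.index[truth.isin(["duplicate_source", "duplicate"])])
    for s, d in truth.items():
        if s in pair:
            continue
        assert s in report.removed_samples, f"{s} ({d}) not removed"
    # exactly one member of the duplicate pair is dropped, whichever it is
    assert len(pair & set(report.removed_samples)) == 1
    assert set(report.removed_samples) <= set(truth.index)  # no false flags
    assert len(report.retained_samples) == G.n_samples - (len(truth) - 1)
    # retained SNPs satisfy the recomputed-MAF contract
    assert (clean.empirical_maf() >= 0.15).all()
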