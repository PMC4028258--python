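import numpy as np
import pandas as pd
import pytest

from hearteqtl.datatypes import ValidationError
from hearteqtl.mapping import (
    ScanConfig,
    bh_stepup,
    build_design,
    classify_relation,
    fit_eqtl,
    ld_prune,
    ld_r2,
    run_scan,
    signed_distance,
    storey_pi0,
    storey_qvalues,
)
from hearteqtl.simulate import make_covariates

from conftest import small_config, toy_genotypes


def test_fit_eqtl_exact_fit():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.4, size=20).astype(float)
    y = 2.0 * d
    fit = fit_eqtl(y, d)
    assert fit["beta"] == pytest.approx(2.0, abs=1e-12)
    assert fit["p"] <= 1e-250  # at the numeric floor up to lstsq round-off


def test_fit_eqtl_zero_variance_dosage():
    with pytest.raises(ValidationError, match="variance"):
        fit_eqtl(np.random.default_rng(1).normal(size=10), np.ones(10))


def test_fit_eqtl_collinear_covariate_named():
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.3, size=30).astype(float)
    y = rng.normal(size=30)
    X = pd.DataFrame({"a": rng.normal(size=30)})
    X["b"] = 2 * X["a"]
    with pytest.raises(ValidationError, match="b"):
        fit_eqtl(y, d, X)


def test_fit_eqtl_null_p_uniform():
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(2000):
        d = rng.binomial(2, 0.3, size=50).astype(float)
        if d.var() == 0:
            continue
        y = rng.normal(size=50)
        ps.append(fit_eqtl(y, d)["p"])
    from scipy.stats import kstest

    assert kstest(ps, "uniform").pvalue > 0.01


def test_signed_distance_upstream_plus():
    assert signed_distance(259648, 260118, 300000, "+") == (-470, "upstream")


def test_signed_distance_upstream_minus():
    assert signed_distance(70395945, 69400000, 69434245, "-") == (-961700, "upstream")


def test_signed_distance_inside_and_boundaries():
    assert signed_distance(150, 100, 200, "+") == (0, "inside")
    assert signed_distance(100, 100, 200, "+") == (0, "inside")  # snp at TSS
    assert signed_distance(250, 100, 200, "+") == (50, "downstream")
    assert signed_distance(50, 100, 200, "-") == (50, "downstream")
    assert signed_distance(250, 100, 200, "-") == (-50, "upstream")


def test_signed_distance_errors():
    with pytest.raises(ValidationError):
        signed_distance(5, 1, 10, "+", snp_chrom="1", gene_chrom="2")
    with pytest.raises(ValidationError):
        signed_distance(5, 10, 1, "+")
    with pytest.raises(ValidationError):
        signed_distance(5, 1, 10, "x")


def test_classify_relation_boundaries():
    assert classify_relation("1", 2_000_000, "1", 1_000_000) == "cis"
    assert classify_relation("1", 2_000_001, "1", 1_000_000) == "trans"
    assert classify_relation("1", 1_000_000, "2", 1_000_000) == "trans"


def test_bh_hand_example():
    p_adj, reject = bh_stepup(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
    np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04])
    assert reject.all()


def test_bh_trivia():
    p_adj, _ = bh_stepup(np.array([0.2]))
    assert p_adj[0] == 0.2
    p_adj, _ = bh_stepup(np.full(5, 0.3))
    np.testing.assert_allclose(p_adj, 0.3)


def test_storey_all_half():
    q = storey_qvalues(np.full(10, 0.5), pi0=1.0)
    np.testing.assert_allclose(q, 0.5)


def test_storey_pi0_near_one_under_null():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=10_000)
    assert 0.9 <= storey_pi0(p) <= 1.0


def test_storey_small_m_warns_bh_fallback():
    p = np.array([0.01, 0.2, 0.8])
    with pytest.warns(UserWarning):
        q = storey_qvalues(p)
    expected, _ = bh_stepup(p)
    np.testing.assert_allclose(q, expected)


def test_ld_r2_conventions():
    d = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
    assert ld_r2(d, d) == pytest.approx(1.0)
    assert ld_r2(d, 2.0 - d) == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        assert ld_r2(d, np.ones(6)) == 0.0


def test_ld_prune_trivial_cases():
    rng = np.random.default_rng(6)
    base = rng.binomial(2, 0.4, size=200).astype(float)
    perfect = np.tile(base[:, None], (1, 5))
    G = toy_genotypes(perfect)
    records = pd.DataFrame(
        {"snp": list(G.snp_ids), "probe": "pX", "p": [0.03, 0.01, 0.02, 0.05, 0.04]}
    )
    clusters = ld_prune(records, G)
    assert len(clusters) == 1
    assert clusters[0].top_snp == "v1"  # lowest p

    indep = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
    G2 = toy_genotypes(indep)
    clusters2 = ld_prune(records, G2)
    assert len(clusters2) == 5
    assert all(len(c.snp_ids) == 1 for c in clusters2)


def test_ld_prune_does_not_link_across_chromosomes():
    rng = np.random.default_rng(7)
    base = rng.binomial(2, 0.4, size=100).astype(float)
    d = np.tile(base[:, None], (1, 2))
    G = toy_genotypes(d, chrom=["1", "2"])
    records = pd.DataFrame({"snp": list(G.snp_ids), "probe": "pX", "p": [0.01, 0.02]})
    assert len(ld_prune(records, G)) == 2


def test_run_scan_misaligned_samples_error(small_cohort):
    G, E, covars, cfg = small_cohort
    bad = covars.iloc[:-1]
    with pytest.raises(ValidationError, match="mismatch"):
        run_scan(G, E, bad)


def test_run_scan_matches_fit_eqtl_per_pair(small_cohort):
    G, E, covars, cfg = small_cohort
    result = run_scan(G.subset(snps=G.snp_ids[:50]), E.subset(probes=E.probe_ids[:10]),
                      covars)
    X = build_design(covars)
    cis = result.cis_pvalues
    sample = cis.sample(n=min(20, len(cis)), random_state=0)
    for _, row in sample.iterrows():
        fit = fit_eqtl(E.values[row["probe"]], G.dosage[row["snp"]], X)
        assert row["beta"] == pytest.approx(fit["beta"], abs=1e-9)
        assert row["p"] == pytest.approx(fit["p"], rel=1e-9)


def test_run_scan_handles_missing_dosages(small_cohort):
    G, E, covars, cfg = small_cohort
    Gm = G.subset(snps=G.snp_ids[:30])
    dosage = Gm.dosage.copy()
    dosage.iloc[0:3, 0] = np.nan
    from hearteqtl.datatypes import GenotypeMatrix

    Gm = GenotypeMatrix(dosage=dosage, snps=Gm.snps.copy())
    result = run_scan(Gm, E.subset(probes=E.probe_ids[:5]), covars)
    snp = Gm.snp_ids[0]
    probe = E.probe_ids[0]
    row = result.cis_pvalues.query("snp == @snp and probe == @probe")
    if len(row):
        fit = fit_eqtl(E.values[probe], Gm.dosage[snp], build_design(covars))
        assert row["p"].iloc[0] == pytest.approx(fit["p"], rel=1e-9)
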