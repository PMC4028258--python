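import numpy as np
import pandas as pd
import pytest

from hearteqtl.datatypes import ValidationError
from hearteqtl.gwas import (
    annotate_tss_distance,
    bonferroni_threshold,
    enrichment,
    matched_random_sets,
    nominal_snp_counts,
    nominal_snp_indicator,
    prune_gwas_loci,
)
from hearteqtl.gwas import test_gwas_snps as gwas_locus_tests  # not a pytest test
from hearteqtl.mapping import build_design, fit_eqtl

from conftest import toy_genotypes


def test_bonferroni_published_counts():
    thr, n = bonferroni_threshold(0.05, 64, 18_402)
    assert n == 1_177_728
    # ~4e-8 at one significant figure
    assert float(f"{thr:.0e}") == 4e-8
    thr2, _ = bonferroni_threshold(0.05, 1, 1)
    assert thr2 == 0.05
    thr3, _ = bonferroni_threshold(0.05, 1_000, 1_000)
    assert thr3 == 0.05 / 1_000_000
    assert thr3 == pytest.approx(5e-8, rel=1e-12)


def test_enrichment_worked_example():
    res = enrichment(4, [1, 2, 4, 1])
    assert res.fold == pytest.approx(2.75)
    assert res.p_emp == pytest.approx(0.4)
    assert res.n_sets == 4


def test_enrichment_degenerate_conventions():
    res = enrichment(3, [3, 3, 3])
    assert res.fold == pytest.approx(1.0)
    assert res.p_emp == pytest.approx(1.0)
    res0 = enrichment(2, [0, 0, 0, 0])
    assert res0.fold == pytest.approx(2 / 0.5)
    assert res0.p_emp == pytest.approx(1 / 5)
    assert res0.n_substituted == 4
    with pytest.raises(ValidationError):
        enrichment(-1, [1])
    with pytest.raises(ValidationError):
        enrichment(1, [])


def test_prune_gwas_loci_with_r2_table():
    gwas = pd.DataFrame(
        {"snp": ["a", "b", "c"], "chrom": ["1", "1", "2"],
         "pos": [100, 200, 300], "trait": "t", "p_gwas": [1e-9, 1e-10, 1e-8]}
    )
    r2 = pd.DataFrame(0.0, index=["a", "b", "c"], columns=["a", "b", "c"])
    r2.loc["a", "b"] = r2.loc["b", "a"] = 0.9
    loci = prune_gwas_loci(gwas, r2_table=r2)
    assert len(loci) == 2
    joint = next(L for L in loci if len(L["snps"]) == 2)
    assert set(joint["snps"]) == {"a", "b"}
    assert joint["lead"] == "b"  # lower source p


def test_prune_gwas_loci_orphan_warns():
    gwas = pd.DataFrame({"snp": ["x"], "chrom": ["1"], "pos": [1],
                         "trait": "t", "p_gwas": [1e-9]})
    with pytest.warns(UserWarning, match="x"):
        loci = prune_gwas_loci(gwas)
    assert len(loci) == 1


def _assoc_fixture(seed=0, n=80, m=6, p=4):
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    G = toy_genotypes(d)
    from conftest import toy_expression

    vals = rng.normal(8, 1, size=(n, p))
    E = toy_expression(vals)
    covars = pd.DataFrame(
        {"age": rng.integers(20, 70, size=n).astype(float),
         "sex": rng.choice(["M", "F"], size=n),
         "center": rng.choice(["c1", "c2"], size=n)},
        index=G.sample_ids,
    )
    return G, E, covars


def test_gwas_snps_zero_loci_gives_empty_tables():
    G, E, covars = _assoc_fixture()
    table, nominal, Q, thr = gwas_locus_tests([], G, E, covars)
    assert len(table) == 0 and len(nominal) == 0
    assert Q == 0 and np.isnan(thr)


def test_gwas_snps_planted_effect_is_nominal():
    G, E, covars = _assoc_fixture(seed=1)
    vals = E.values.copy()
    vals["p0"] = vals["p0"] + 0.8 * G.dosage["v0"]
    from conftest import toy_expression

    E2 = toy_expression(vals.to_numpy())
    loci = [{"snps": ["v0"], "lead": "v0"}]
    table, nominal, Q, thr = gwas_locus_tests(loci, G, E2, covars)
    assert ((nominal["snp"] == "v0") & (nominal["probe"] == "p0")).any()
    assert Q == 1


def test_gwas_snps_count_levels_and_missing_locus():
    G, E, covars = _assoc_fixture(seed=2)
    loci = [{"snps": ["v0"], "lead": "v0"}, {"snps": ["zz"], "lead": "zz"}]
    with pytest.warns(UserWarning, match="zz"):
        table, nominal, Q, thr = gwas_locus_tests(loci, G, E, covars, count_level="pair")
    assert Q == len(nominal)
    # threshold reflects the single kept locus
    assert thr == pytest.approx(0.05 / (1 * len(E.probe_ids)))


def test_annotate_tss_distance():
    G, E, covars = _assoc_fixture()
    snps = G.snps.copy()
    dist = annotate_tss_distance(snps, E.probes)
    # nearest-TSS by brute force
    for sid, row in snps.iterrows():
        tss = E.probes.loc[E.probes["chrom"] == row["chrom"], "tss"]
        expected = (tss - row["pos"]).abs().min() if len(tss) else np.inf
        assert dist[sid] == expected
    off = snps.copy()
    off["chrom"] = "99"
    assert np.isinf(annotate_tss_distance(off, E.probes)).all()


def test_matched_sets_forced_pool_is_permutation():
    pool = pd.DataFrame(
        {"maf": [0.2, 0.21, 0.22], "tss_dist": [5e3, 6e3, 7e3]},
        index=pd.Index(["a", "b", "c"], name="snp"),
    )
    sets = matched_random_sets(pool, ["a", "b", "c"], 20, seed=0)
    for s in sets:
        assert sorted(s) == ["a", "b", "c"]


def test_matched_sets_respect_bins_and_determinism():
    rng = np.random.default_rng(8)
    pool = pd.DataFrame(
        {"maf": rng.uniform(0.05, 0.5, size=400),
         "tss_dist": rng.uniform(0, 2e6, size=400)},
        index=pd.Index([f"s{i}" for i in range(400)], name="snp"),
    )
    targets = list(pool.index[:5])
    sets = matched_random_sets(pool, targets, 10, seed=1)
    from hearteqtl.gwas import MAF_BIN_WIDTH, TSS_DIST_EDGES, _bin_ids

    bins = _bin_ids(pool["maf"], pool["tss_dist"], MAF_BIN_WIDTH, TSS_DIST_EDGES)
    want = sorted(bins.loc[targets])
    for s in sets:
        assert sorted(bins.loc[s]) == want
        assert len(set(s)) == len(s)  # without replacement
    assert matched_random_sets(pool, targets, 10, seed=1) == sets
    assert matched_random_sets(pool, targets, 10, seed=2) != sets


def test_matched_sets_thin_bin_error():
    pool = pd.DataFrame(
        {"maf": [0.05, 0.45], "tss_dist": [1e3, 1e3]},
        index=pd.Index(["a", "b"], name="snp"),
    )
    with pytest.raises(ValidationError, match="bin"):
        matched_random_sets(pool, ["a", "a"], 5, seed=0)


def test_nominal_counts_match_fit_eqtl():
    G, E, covars = _assoc_fixture(seed=3, n=60, m=5, p=6)
    counts = nominal_snp_counts(G, E, covars, 0.05)
    X = build_design(covars)
    for snp in G.snp_ids:
        expected = sum(
            fit_eqtl(E.values[p], G.dosage[snp], X)["p"] <= 0.05 for p in E.probe_ids
        )
        assert counts[snp] == expected
    flags = nominal_snp_indicator(G, E, covars, 0.05)
    assert (flags == (counts > 0)).all()
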