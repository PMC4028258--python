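import numpy as np
import pandas as pd
import pytest

from hearteqtl.datatypes import ExpressionMatrix, GenotypeMatrix
from hearteqtl.simulate import (
    SimulationConfig,
    make_covariates,
    make_probe_annotation,
    simulate_expression,
    simulate_genotypes,
)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_samples=60,
        n_snps=300,
        n_probes=40,
        n_y_probes=4,
        n_chromosomes=2,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    G = simulate_genotypes(cfg)
    probes = make_probe_annotation(cfg, G.snps)
    covars = make_covariates(cfg)
    E = simulate_expression(G, probes, covars, cfg)
    return G, E, covars, cfg


def toy_genotypes(dosage: np.ndarray, chrom=None, pos=None, rsq=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw samples x SNPs dosage array."""
    n, m = dosage.shape
    samples = [f"S{i}" for i in range(n)]
    snps = [f"v{j}" for j in range(m)]
    anno = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "minor_allele": ["A"] * m,
            "major_allele": ["G"] * m,
            "maf": np.nanmean(dosage, axis=0) / 2,
            "imputation_rsq": rsq if rsq is not None else [np.nan] * m,
        },
        index=pd.Index(snps, name="snp"),
    )
    dm = pd.DataFrame(dosage, index=pd.Index(samples, name="sample"), columns=anno.index)
    return GenotypeMatrix(dosage=dm, snps=anno)


def toy_expression(values: np.ndarray, probes: pd.DataFrame = None) -> ExpressionMatrix:
    """ExpressionMatrix from a raw samples x probes array."""
    n, m = values.shape
    samples = [f"S{i}" for i in range(n)]
    if probes is None:
        probes = pd.DataFrame(
            {
                "gene": [f"G{j}" for j in range(m)],
                "chrom": ["1"] * m,
                "strand": ["+"] * m,
                "gene_start": np.arange(1, m + 1) * 10_000,
                "gene_end": np.arange(1, m + 1) * 10_000 + 5000,
                "tss": np.arange(1, m + 1) * 10_000,
                "contains_snp": [False] * m,
                "ambiguous_mapping": [False] * m,
            },
            index=pd.Index([f"p{j}" for j in range(m)], name="probe"),
        )
    vm = pd.DataFrame(values, index=pd.Index(samples, name="sample"), columns=probes.index)
    return ExpressionMatrix(values=vm, probes=probes)
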