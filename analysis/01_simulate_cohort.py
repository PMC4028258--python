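"""Generate the synthetic left-ventricle eQTL cohort.

154 genotyped donors with HWE genotypes in LD blocks, log2 expression with
20 planted cis effects and 1 trans effect (|beta| 0.2-2.0 per minor-allele
copy), age/sex/center covariate structure, Y-chromosome probes, and 25
deliberately defective samples (13 allele-frequency-shifted outliers, 4 low
call rate, 4 duplicates, 2+2 heterozygosity extremes) so the QC stages have
ground truth to find.  Writes genotype/expression/annotation/covariate TSVs
plus the defect and planted-effect truth tables under results/run/.
"""

import pathlib
import sys

import pandas as pd

from hearteqtl import io, pipeline
from hearteqtl.simulate import make_gwas_list

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    cfg = pipeline.merge_config({"seed": seed})
    G, E, covars, labels = pipeline.stage_simulate(cfg, OUT)
    planted = pd.read_csv(OUT / "planted_effects.tsv", sep="\t")
    gwas = make_gwas_list(G, planted, seed=seed)
    io.write_gwas_tsv(gwas, OUT / "gwas_snps.tsv")
    print(f"cohort: {G.n_samples} samples x {G.n_snps} SNPs x {len(E.probe_ids)} probes")
    print(f"defective samples: {labels['sample'].nunique()} "
          f"({labels['defect'].value_counts().to_dict()})")
    print(f"planted effects: {len(planted)} ({(planted['kind'] == 'cis').sum()} cis)")
    print(f"GWAS list: {len(gwas)} SNPs ({len(set(gwas['snp']) & set(planted['snp']))} "
          f"true eQTL SNPs) -> {OUT / 'gwas_snps.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
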