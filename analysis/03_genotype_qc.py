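"""Genotype QC cascade: call rate, IBS duplicates, heterozygosity, stratification.

Runs the full sample filter cascade on the simulated cohort and compares
flags against the injected ground truth, then applies the SNP filters
(MAF >= 0.15 recomputed on the clean samples, imputation rsq >= 0.30).
"""

import pathlib
import sys

import pandas as pd

from hearteqtl import pipeline

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    cfg = pipeline.merge_config({"seed": seed})
    clean, report = pipeline.stage_genotype_qc(cfg, OUT)
    labels = pd.read_csv(OUT / "defect_labels.tsv", sep="\t").set_index("sample")["defect"]
    reasons = pd.Series(list(report.removed_samples.values())).value_counts()
    print(f"samples: {len(report.sample_stats)} -> {len(report.retained_samples)}")
    print(f"removed by reason: {reasons.to_dict()}")
    false_flags = [s for s in report.removed_samples if s not in labels.index]
    # a retained duplicate partner is fine: only one member of a pair is removed
    missed = [
        (s, d) for s, d in labels.items()
        if s not in report.removed_samples
        and d not in ("duplicate_source", "duplicate", "expression_outlier")
    ]
    print(f"false flags: {false_flags or 'none'}; missed defects: {missed or 'none'}")
    print(f"SNPs: {len(report.snp_stats)} -> {len(report.retained_snps)} after MAF/rsq filters")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
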