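"""Genome-wide eQTL scan with LD pruning.

Tests every SNP x transcript pair with the additive covariate-adjusted
model, corrects cis tests with Storey q-values (q <= 0.05) and trans tests
with the 5e-8 floor + Benjamini-Hochberg, prunes significant SNPs into
independent LD clusters (r2 > 0.6), and checks how many planted effects
were recovered.
"""

import pathlib
import sys

import pandas as pd

from hearteqtl import pipeline

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    cfg = pipeline.merge_config({"seed": seed})
    result, clusters = pipeline.stage_scan(cfg, OUT)
    rec = result.records
    print(f"tests: {result.n_tests} ({result.n_cis_tests} cis, {result.n_trans_tests} trans)")
    print(f"pi0 estimate over cis p-values: {result.pi0:.3f}")
    print(f"significant records: {len(rec)} over {rec['probe'].nunique()} transcripts; "
          f"cis p threshold at q<=0.05: {result.cis_p_threshold:.3g}")
    print(f"independent LD clusters: {len(clusters)}")
    planted = pd.read_csv(OUT / "planted_effects.tsv", sep="\t")
    tested_probes = set(pd.read_csv(OUT / "probe_annotation_qc.tsv", sep="\t")["probe"])
    testable = planted[planted["probe"].isin(tested_probes)]
    hit = testable["probe"].isin(set(rec["probe"]))
    print(f"planted effects recovered: {hit.sum()}/{len(testable)} testable "
          f"({len(planted) - len(testable)} planted probes removed by expression QC)")
    top = pd.DataFrame(
        [
            {"cluster": c.cluster_id, "top_snp": c.top_snp, "n_snps": len(c.snp_ids),
             **c.representative_records().iloc[0][["gene", "p", "beta", "maf",
                                                   "distance", "position_label"]].to_dict()}
            for c in clusters[:10]
        ]
    )
    print("top clusters:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
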