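"""Power analysis over MAF and effect size at FDR 0.05.

Simulates eQTL populations at each minimum MAF level (0.05-0.40), tests
with the additive model, BH-corrects at FDR 0.05, and tabulates the
conditional power: the fraction of eQTLs with |log2 fold change| > X that
were rejected.  The design claim this supports: at n = 129, MAF >= 0.15
gives materially better power than lower frequencies across mid-range
effect sizes.
"""

import pathlib
import sys

from hearteqtl import pipeline

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    cfg = pipeline.merge_config({"seed": seed, "power": {"n_eqtls": 2000, "reps": 3}})
    table = pipeline.stage_power(cfg, OUT)
    wide = table.pivot(index="X", columns="maf", values="power").round(3)
    print(f"power at n={cfg['power']['n']}, FDR {cfg['power']['fdr']} "
          "(rows: min |log2 FC| X, columns: MAF):")
    print(wide.to_string())
    mid = wide.loc[0.5]
    print(f"at X=0.5: power rises from {mid[0.05]:.2f} (MAF 0.05) to "
          f"{mid[0.15]:.2f} (MAF 0.15) and {mid[0.40]:.2f} (MAF 0.40)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
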