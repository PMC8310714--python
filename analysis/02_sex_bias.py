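#!/usr/bin/env python
"""Call sex-biased genes per species and organ and summarize sharing.

Expects the dataset from 01_simulate.py; writes sex_bias.tsv, qc_flags.tsv,
sbg_sharing.tsv and variance_check.tsv under results/run/results/ and prints
the organ-level SBG landscape.
"""

from pathlib import Path

import pandas as pd

from sbgevo.pipeline import PipelineConfig, run_pipeline
from sbgevo.simulate import SimulationConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(outdir=str(OUT), sim=SimulationConfig(seed=seed),
                         stages=("simulate", "de"))
    run_pipeline(cfg)
    bias = pd.read_csv(OUT / "results" / "sex_bias.tsv", sep="\t", comment="#")
    frac = (bias.assign(sbg=bias["direction"] != "unbiased")
            .groupby("organ")["sbg"].mean() * 100)
    print("percent SBGs among tested genes, by organ:")
    print(frac.round(2).to_string())
    share = pd.read_csv(OUT / "results" / "sbg_sharing.tsv", sep="\t",
                        comment="#")
    print("\ncross-species sharing of SBG status:")
    print(share.to_string(index=False))


if __name__ == "__main__":
    main()
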