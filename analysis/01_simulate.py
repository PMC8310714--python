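#!/usr/bin/env python
"""Generate the synthetic comparative RNA-seq study.

Fourteen species on a Yule tree, five organs, three replicates per sex and
organ, plus genotypes, coding sequences and traits. Writes the dataset and
its truth tables under results/run/data/.
"""

from pathlib import Path

from sbgevo.simulate import SimulationConfig, simulate_dataset, write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed)
    ds = simulate_dataset(cfg)
    files = write_dataset(ds, OUT / "data")
    n_sbg = len(ds.truth["sbg"])
    print(f"simulated {cfg.n_species} species x {len(cfg.organs)} organs, "
          f"{cfg.n_genes} genes; {n_sbg} planted sex-biased (gene, species, "
          f"organ) entries; {len(files)} files under {OUT / 'data'}")


if __name__ == "__main__":
    main()
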