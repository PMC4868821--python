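#!/usr/bin/env python
"""Generate the reference synthetic experiment used by all later steps.

Writes the expression matrix, annotation tables, allele counts and ground
truth for a five-day experiment under the default study conditions
(two-active-X females), plus matched dampening and X-inactivation runs
for the dosage analyses.
"""

from pathlib import Path

from embryolin.datasets import write_allele_table, write_dataset
from embryolin.simulate import SimConfig, simulate_experiment

OUT = Path("results/data")
SEED = 1


def emit(name: str, config: SimConfig) -> None:
    dataset, alleles, truth = simulate_experiment(config)
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, out / "matrix.tsv", out / "genes.tsv",
                  out / "cells.tsv")
    write_allele_table(alleles, out / "alleles.tsv")
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    print(f"{name}: {dataset.n_genes} genes x {dataset.n_cells} cells, "
          f"{len(alleles)} allele rows")


def main() -> None:
    emit("two_active", SimConfig(seed=SEED))
    emit("dampening", SimConfig(seed=SEED, dosage_mode="dampening"))
    emit("xci", SimConfig(seed=SEED, dosage_mode="xci"))
    print("wrote reference datasets under", OUT)


if __name__ == "__main__":
    main()
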