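#!/usr/bin/env python
"""Allelic analysis: biallelic fractions distinguish dampening from XCI.

Classifies every (cell, SNV) observation, computes the per-cell
chrX:autosome biallelic-fraction ratio in the dampening and XCI regimes,
and summarises the male chrX maternal-carryover signal at E3.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from embryolin.allelic import (classify_table, male_x_biallelic_zga,
                               relative_biallelic_ratio)
from embryolin.datasets import read_allele_table

OUT = Path("results/08_allelic")


def load(regime):
    base = Path("results/data") / regime
    alleles = read_allele_table(base / "alleles.tsv")
    truth = pd.read_csv(base / "truth_cells.tsv", sep="\t", index_col=0)
    return alleles, truth


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for regime in ("two_active", "dampening", "xci"):
        alleles, truth = load(regime)
        classified = classify_table(alleles)
        rel = relative_biallelic_ratio(classified)
        fem = truth.index[truth["sex"] == "female"]
        days = truth["day"]
        per_day = {}
        for day in sorted(days.unique()):
            sel = rel.reindex(fem[days.loc[fem] == day]).dropna()
            if len(sel):
                per_day[int(day)] = float(np.median(sel))
        summary[regime] = {"female_relative_biallelic_by_day": per_day}
        if regime == "two_active":
            zga = male_x_biallelic_zga(classified, truth)
            summary[regime]["male_chrX_biallelic_e3"] = \
                float(np.median(zga["chrX"][3]))
            summary[regime]["male_chrX_biallelic_e4"] = \
                float(np.median(zga["chrX"][4]))
            summary[regime]["p_e3_vs_e4"] = zga["p_e3_vs_e4"]
        rel.to_csv(OUT / f"relative_biallelic_{regime}.tsv", sep="\t")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print("Dampening keeps the female chrX biallelic fraction at "
          "autosomal levels at every day; XCI drives it toward zero as "
          "whole X copies fall silent — the allelic signature that "
          "separates the two mechanisms.")


if __name__ == "__main__":
    main()
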