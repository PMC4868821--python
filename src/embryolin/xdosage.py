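"""X-chromosome dosage-compensation statistics.

Female and male expression levels are compared gene-by-gene (pseudo-counted
mean ratios for transcribed genes), chromosome-wide (moving averages over
the 25 positionally nearest expressed genes), and per cell (total X output
over a fixed gene set).  Autosomes serve as negative controls throughout —
their female:male ratios should sit at parity in every regime.  An X0
screen flags sex-called-female embryos whose chrX profile tracks the male
reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import ExpressionDataset


def _sex_split(dataset: ExpressionDataset, cells):
    sex = dataset.cells.loc[cells, "sex"]
    female = list(sex.index[sex == "female"])
    male = list(sex.index[sex == "male"])
    return female, male


def gene_time_trend(dataset: ExpressionDataset, days=(4, 5, 6, 7),
                    expressed_threshold: float = 1.0) -> dict:
    """Per-gene Spearman correlation of expression with embryonic day.

    Computed separately in female and male cells over the given days;
    genes must be expressed (mean RPKM ≥ threshold in at least one sex).
    Returns the per-gene table (rho_female, rho_male, chrom_class) plus
    Mann-Whitney comparisons of the chrX rho distributions between sexes
    and of female chrX versus female autosomes.
    """
    cells = dataset.cells.index[dataset.cells["day"].isin(days)]
    female, male = _sex_split(dataset, cells)
    if len(female) == 0 or len(male) == 0:
        raise ValueError("need cells of both sexes")
    bio = dataset.biological()
    day_f = bio.cells.loc[female, "day"].to_numpy(float)
    day_m = bio.cells.loc[male, "day"].to_numpy(float)
    vf = bio.values[female].to_numpy()
    vm = bio.values[male].to_numpy()
    expressed = (vf.mean(axis=1) >= expressed_threshold) | \
                (vm.mean(axis=1) >= expressed_threshold)

    def spearman_rows(v, day):
        ranks = scipy.stats.rankdata(v, axis=1)
        dr = scipy.stats.rankdata(day)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        dr = dr - dr.mean()
        denom = np.sqrt((ranks ** 2).sum(axis=1) * (dr ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (ranks @ dr) / denom
        return rho  # NaN for constant genes: recorded as missing

    rho_f = spearman_rows(vf[expressed], day_f)
    rho_m = spearman_rows(vm[expressed], day_m)
    genes = bio.values.index[expressed]
    chrom = bio.genes.loc[genes, "chrom"]
    cls = np.where(chrom == "chrX", "chrX",
                   np.where(chrom == "chrY", "chrY", "autosome"))
    table = pd.DataFrame({"rho_female": rho_f, "rho_male": rho_m,
                          "chrom_class": cls}, index=genes)
    x = table[table["chrom_class"] == "chrX"].dropna()
    a = table[table["chrom_class"] == "autosome"].dropna()
    tests = {}
    if len(x) >= 3:
        tests["p_x_female_vs_male"] = float(scipy.stats.mannwhitneyu(
            x["rho_female"], x["rho_male"], alternative="two-sided").pvalue)
    if len(x) >= 3 and len(a) >= 3:
        tests["p_female_x_vs_autosome"] = float(scipy.stats.mannwhitneyu(
            x["rho_female"], a["rho_female"],
            alternative="two-sided").pvalue)
        tests["p_male_x_vs_autosome"] = float(scipy.stats.mannwhitneyu(
            x["rho_male"], a["rho_male"], alternative="two-sided").pvalue)
    return {"table": table, "tests": tests}


def fm_ratio_per_gene(dataset: ExpressionDataset, day: int,
                      lineage: str | None = None,
                      calls: pd.DataFrame | None = None,
                      expressed_threshold: float = 1.0,
                      pseudocount: float = 1.0) -> dict:
    """Per-gene female:male expression ratios within a day (and lineage).

    A gene is transcribed when its mean RPKM is ≥ threshold in at least
    one sex within the stratum; its ratio is
    (mean_female + pc) / (mean_male + pc).  Returns the per-gene table,
    the chrX and autosomal medians and a Mann-Whitney comparison of the
    chrX ratio distribution against the autosomal one.
    """
    cells = dataset.cells.index[dataset.cells["day"] == day]
    if lineage is not None:
        if calls is None:
            raise ValueError("lineage stratification needs lineage calls")
        cells = cells[calls.loc[cells, "lineage"] == lineage]
    female, male = _sex_split(dataset, cells)
    if len(female) == 0 or len(male) == 0:
        raise ValueError(f"empty sex stratum at day {day}")
    bio = dataset.biological()
    mf = bio.values[female].mean(axis=1)
    mm = bio.values[male].mean(axis=1)
    transcribed = (mf >= expressed_threshold) | (mm >= expressed_threshold)
    ratio = (mf[transcribed] + pseudocount) / (mm[transcribed] + pseudocount)
    chrom = bio.genes.loc[ratio.index, "chrom"]
    cls = pd.Series(np.where(chrom == "chrX", "chrX",
                             np.where(chrom == "chrY", "chrY", "autosome")),
                    index=ratio.index)
    table = pd.DataFrame({"ratio": ratio, "chrom_class": cls})
    x = table.loc[table["chrom_class"] == "chrX", "ratio"]
    a = table.loc[table["chrom_class"] == "autosome", "ratio"]
    p = None
    if len(x) >= 3 and len(a) >= 3:
        p = float(scipy.stats.mannwhitneyu(x, a,
                                           alternative="two-sided").pvalue)
    return {"table": table,
            "chrX_median": float(np.median(x)) if len(x) else float("nan"),
            "autosome_median": float(np.median(a)) if len(a) else
            float("nan"),
            "p_x_vs_autosome": p}


def compare_day_ratios(result_a: dict, result_b: dict) -> float:
    """Mann-Whitney p for chrX ratio distributions of two strata
    (e.g. a later day versus E4)."""
    xa = result_a["table"].query("chrom_class == 'chrX'")["ratio"]
    xb = result_b["table"].query("chrom_class == 'chrX'")["ratio"]
    return float(scipy.stats.mannwhitneyu(
        xa, xb, alternative="two-sided").pvalue)


@dataclasses.dataclass
class DoseTrack:
    """Moving-average female:male ratio along one chromosome."""
    chrom: str
    gene_ids: list
    positions: np.ndarray     # sorted ascending
    ratio: np.ndarray
    window: int


def moving_average_track(dataset: ExpressionDataset, chrom: str, day: int,
                         window: int = 25,
                         expressed_threshold: float = 1.0,
                         pseudocount: float = 1.0,
                         cells=None) -> DoseTrack:
    """Female:male moving average over the ``window`` nearest expressed
    genes along a chromosome.

    Genes are ordered by start position; at each gene the window covers
    the ``window`` positionally nearest expressed genes (in chromosome
    rank, sliding inside the ends), and the track value is the ratio of
    the windowed female mean to the windowed male mean (pseudo-counted).
    """
    if cells is None:
        cells = dataset.cells.index[dataset.cells["day"] == day]
    female, male = _sex_split(dataset, cells)
    if len(female) == 0 or len(male) == 0:
        raise ValueError("need cells of both sexes")
    bio = dataset.biological()
    on_chrom = bio.genes.index[bio.genes["chrom"] == chrom]
    mf = bio.values.loc[on_chrom, female].mean(axis=1)
    mm = bio.values.loc[on_chrom, male].mean(axis=1)
    expressed = (mf >= expressed_threshold) | (mm >= expressed_threshold)
    genes = on_chrom[expressed]
    if len(genes) < window:
        raise ValueError(f"only {len(genes)} expressed genes on {chrom}, "
                         f"window is {window}")
    pos = bio.genes.loc[genes, "start"].to_numpy()
    order = np.lexsort((np.asarray(genes), pos))
    genes = genes[order]
    pos = pos[order]
    f = mf[genes].to_numpy()
    m = mm[genes].to_numpy()
    n = len(genes)
    ratio = np.empty(n)
    half = (window - 1) // 2
    for i in range(n):
        lo = min(max(0, i - half), n - window)
        wf = f[lo:lo + window].mean()
        wm = m[lo:lo + window].mean()
        ratio[i] = (wf + pseudocount) / (wm + pseudocount)
    return DoseTrack(chrom=chrom, gene_ids=list(genes), positions=pos,
                     ratio=ratio, window=window)


def total_x_output(dataset: ExpressionDataset, fixed_gene_set) -> dict:
    """Per-cell chrX RPKM sum over a fixed gene set, by sex and day.

    The gene set is fixed across days (typically the intersection of
    expressed chrX genes at all days) so that day-to-day comparisons are
    not confounded by gene-set drift.  Returns the per-cell table and MWW
    tests: female E4 vs female E7 and female vs male per day.
    """
    fixed_gene_set = list(fixed_gene_set)
    if not fixed_gene_set:
        raise ValueError("empty gene set")
    sums = dataset.values.loc[fixed_gene_set].sum(axis=0)
    table = pd.DataFrame({"x_sum": sums,
                          "sex": dataset.cells["sex"],
                          "day": dataset.cells["day"]})
    tests = {}
    f4 = table.query("sex == 'female' and day == 4")["x_sum"]
    f7 = table.query("sex == 'female' and day == 7")["x_sum"]
    if len(f4) >= 3 and len(f7) >= 3:
        tests["p_female_e4_vs_e7"] = float(scipy.stats.mannwhitneyu(
            f4, f7, alternative="two-sided").pvalue)
    for day in sorted(table["day"].unique()):
        f = table.query("sex == 'female' and day == @day")["x_sum"]
        m = table.query("sex == 'male' and day == @day")["x_sum"]
        if len(f) >= 3 and len(m) >= 3:
            tests[f"p_f_vs_m_day{day}"] = float(scipy.stats.mannwhitneyu(
                f, m, alternative="two-sided").pvalue)
    return {"table": table, "tests": tests}


def fixed_expressed_gene_set(dataset: ExpressionDataset, chrom: str = "chrX",
                             expressed_threshold: float = 1.0) -> list:
    """Genes on ``chrom`` expressed (mean RPKM ≥ threshold) at every day."""
    bio = dataset.biological()
    on_chrom = bio.genes.index[bio.genes["chrom"] == chrom]
    keep = pd.Series(True, index=on_chrom)
    for day in sorted(bio.cells["day"].unique()):
        cells = bio.cells.index[bio.cells["day"] == day]
        keep &= bio.values.loc[on_chrom, cells].mean(axis=1) >= \
            expressed_threshold
    return list(on_chrom[keep])


def gene_fraction_above(dataset: ExpressionDataset, gene: str,
                        thresholds) -> pd.DataFrame:
    """Fraction of cells with the gene's RPKM above each threshold,
    stratified by sex and day.  Monotone non-increasing in threshold."""
    if gene not in dataset.genes.index:
        raise ValueError(f"gene {gene!r} not in dataset")
    vals = dataset.values.loc[gene]
    rows = []
    for (sex, day), members in dataset.cells.groupby(
            ["sex", "day"]).groups.items():
        v = vals.loc[members]
        for thr in thresholds:
            rows.append((sex, int(day), float(thr),
                         float((v > thr).mean())))
    return pd.DataFrame(rows, columns=["sex", "day", "threshold",
                                       "fraction"])


def x0_screen(dataset: ExpressionDataset, embryo: str, window: int = 25,
              closer_frac: float = 0.8) -> dict:
    """Screen one embryo for a suspected X0 karyotype.

    The embryo's chrX moving-average profile is compared position-by-
    position (on log scale) with same-day female and male reference
    profiles built from the other embryos.  A sex-called-female embryo
    closer to the male reference over ≥80% of positions is flagged; male
    embryos are skipped (not applicable).
    """
    cells = dataset.cells
    members = cells.index[cells["embryo_id"] == embryo]
    if len(members) == 0:
        raise ValueError(f"unknown embryo {embryo!r}")
    day = int(cells.loc[members, "day"].iloc[0])
    sexes = cells.loc[members, "sex"].mode()
    embryo_sex = sexes.iloc[0] if len(sexes) else "unknown"
    if embryo_sex != "female":
        return {"embryo": embryo, "applicable": False, "flagged": False}
    day_cells = cells.index[(cells["day"] == day)
                            & (cells["embryo_id"] != embryo)]
    ref_f = day_cells[cells.loc[day_cells, "sex"] == "female"]
    ref_m = day_cells[cells.loc[day_cells, "sex"] == "male"]
    if len(ref_f) == 0 or len(ref_m) == 0:
        raise ValueError("reference embryos of both sexes are required")

    bio = dataset.biological()
    on_x = bio.genes.index[bio.genes["chrom"] == "chrX"]
    prof_e = bio.values.loc[on_x, members].mean(axis=1)
    prof_f = bio.values.loc[on_x, ref_f].mean(axis=1)
    prof_m = bio.values.loc[on_x, ref_m].mean(axis=1)
    expressed = (prof_f >= 1.0) | (prof_m >= 1.0)
    genes = on_x[expressed]
    if len(genes) < window:
        raise ValueError("too few expressed chrX genes for the window")
    pos = bio.genes.loc[genes, "start"].to_numpy()
    order = np.argsort(pos, kind="stable")
    genes = genes[order]

    def windowed(profile):
        v = profile[genes].to_numpy()
        n = len(v)
        half = (window - 1) // 2
        out = np.empty(n)
        for i in range(n):
            lo = min(max(0, i - half), n - window)
            out[i] = v[lo:lo + window].mean()
        return np.log2(out + 1.0)

    we, wf, wm = windowed(prof_e), windowed(prof_f), windowed(prof_m)
    closer_male = np.abs(we - wm) < np.abs(we - wf)
    frac = float(closer_male.mean())
    return {"embryo": embryo, "applicable": True,
            "flagged": frac >= closer_frac, "frac_closer_male": frac,
            "positions": bio.genes.loc[genes, "start"].to_numpy(),
            "track": we, "female_ref": wf, "male_ref": wm}
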