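"""Allele-specific expression calls and biallelic-fraction statistics.

Each (cell, SNV) observation is classified from its reference/alternative
read counts as undetected (too few reads), biallelic (the minor allele is
seen at ≥2 reads and ≥10% of reads) or monoallelic for the major allele.
The discriminating statistic between biallelic dampening and conventional
X inactivation is the per-cell ratio of the chrX biallelic fraction to the
autosomal one: dampening keeps chrX at autosomal levels while XCI drives
it down as whole X copies fall silent.  Reference/alternative labels are
arbitrary (parental phase unknown), so every statistic here is phase-free.

The detection and biallelic thresholds are reconstructions (the original
cutoffs are not published at this level of detail); they are exposed as
parameters and the regime discrimination is required to be robust across a
minor-fraction sensitivity grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


def classify_snv(ref_reads, alt_reads, min_reads: int = 3,
                 minor_min_reads: int = 2, minor_min_frac: float = 0.1):
    """Classify one (cell, SNV) observation.

    Returns ``(call, ratio)``: call ∈ {undetected, mono_ref, mono_alt,
    biallelic}; ratio = alt/(ref+alt) when detected, else None.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("negative read counts")
    total = ref_reads + alt_reads
    if total < min_reads:
        return "undetected", None
    ratio = alt_reads / total
    minor = min(ref_reads, alt_reads)
    if minor >= minor_min_reads and minor / total >= minor_min_frac:
        return "biallelic", ratio
    if alt_reads > ref_reads:
        return "mono_alt", ratio
    return "mono_ref", ratio


def classify_table(table: pd.DataFrame, min_reads: int = 3,
                   minor_min_reads: int = 2,
                   minor_min_frac: float = 0.1) -> pd.DataFrame:
    """Vectorised :func:`classify_snv` over an allele-count table."""
    ref = table["ref_reads"].to_numpy()
    alt = table["alt_reads"].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("negative read counts")
    total = ref + alt
    minor = np.minimum(ref, alt)
    detected = total >= min_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
        ratio = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    biallelic = detected & (minor >= minor_min_reads) & \
        (frac >= minor_min_frac)
    call = np.where(~detected, "undetected",
                    np.where(biallelic, "biallelic",
                             np.where(alt > ref, "mono_alt", "mono_ref")))
    out = table.copy()
    out["call"] = call
    out["ratio"] = np.where(detected, ratio, np.nan)
    return out


def _chrom_mask(chroms: pd.Series, chrom_filter) -> np.ndarray:
    if chrom_filter == "autosome":
        return chroms.isin(AUTOSOMES).to_numpy()
    if isinstance(chrom_filter, str):
        return (chroms == chrom_filter).to_numpy()
    return chroms.isin(list(chrom_filter)).to_numpy()


def biallelic_fraction(classified: pd.DataFrame, cell: str, chrom_filter,
                       min_snvs: int = 25):
    """Biallelic calls / detected calls for one cell, or None.

    ``chrom_filter`` is ``"chrX"``, ``"autosome"``, a chromosome name or a
    list of names.  Cells with fewer than ``min_snvs`` detected SNVs after
    filtering yield None (too little allelic information).
    """
    sub = classified[(classified["cell_id"] == cell)
                     & _chrom_mask(classified["chrom"], chrom_filter)]
    detected = sub[sub["call"] != "undetected"]
    if len(detected) < min_snvs:
        return None
    return float((detected["call"] == "biallelic").mean())


def biallelic_fraction_per_cell(classified: pd.DataFrame, chrom_filter,
                                min_snvs: int = 25) -> pd.Series:
    """Vectorised biallelic fraction for every cell (NaN below min_snvs)."""
    sub = classified[_chrom_mask(classified["chrom"], chrom_filter)]
    det = sub[sub["call"] != "undetected"]
    counts = det.groupby("cell_id").size()
    bi = det.groupby("cell_id")["call"].apply(
        lambda c: (c == "biallelic").mean())
    bi[counts < min_snvs] = np.nan
    return bi


def relative_biallelic_ratio(classified: pd.DataFrame,
                             min_snvs: int = 25,
                             reference: str | tuple = "autosome"
                             ) -> pd.Series:
    """Per-cell chrX biallelic fraction / autosomal biallelic fraction.

    NaN when either fraction is unavailable or the reference fraction is
    zero.  Passing a single chromosome as ``reference`` gives the
    per-chromosome control variant (e.g. chr1 against the rest).
    """
    x = biallelic_fraction_per_cell(classified, "chrX", min_snvs)
    a = biallelic_fraction_per_cell(classified, reference, min_snvs)
    cells = x.index.union(a.index)
    x = x.reindex(cells)
    a = a.reindex(cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = x / a
    ratio[a == 0] = np.nan
    ratio.name = "relative_biallelic_ratio"
    return ratio


def allelic_ratio_histogram(classified: pd.DataFrame, cells, chrom,
                            bins: int = 20):
    """Histogram of alt/(ref+alt) over detected (cell, SNV) pairs."""
    sub = classified[classified["cell_id"].isin(list(cells))
                     & _chrom_mask(classified["chrom"], chrom)]
    ratios = sub.loc[sub["call"] != "undetected", "ratio"].to_numpy()
    counts, edges = np.histogram(ratios, bins=bins, range=(0.0, 1.0))
    return {"counts": counts, "edges": edges, "ratios": ratios}


def gene_allele_barplot_data(table: pd.DataFrame, gene: str, embryos,
                             cell_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell ref/alt counts for one gene, grouped by embryo.

    Every cell of the listed embryos appears; cells without reads over
    the gene's SNVs are flagged ``no_reads`` (they would lack a bar).
    """
    sub = table[table["gene_id"] == gene]
    if len(sub) == 0:
        raise ValueError(f"gene {gene!r} has no SNV in the table")
    embryos = list(embryos)
    cells = cell_table.index[cell_table["embryo_id"].isin(embryos)]
    agg = sub.groupby("cell_id")[["ref_reads", "alt_reads"]].sum()
    out = agg.reindex(cells, fill_value=0)
    out["embryo_id"] = cell_table.loc[out.index, "embryo_id"]
    out["no_reads"] = (out["ref_reads"] + out["alt_reads"]) == 0
    return out.reset_index().rename(columns={"index": "cell_id"})


def male_x_biallelic_zga(classified: pd.DataFrame, cell_table: pd.DataFrame,
                         min_snvs: int = 10) -> dict:
    """Per-day male chrX biallelic fractions (maternal-carryover indicator).

    Lingering maternal transcripts make male chrX reads partially
    biallelic before zygotic genome activation completes; the fraction
    should drop from E3 to E4.  chr1 is carried along as a control.
    Returns per-day Series for chrX and chr1 and the E3-vs-E4 MWW p-value
    (None with a single day).
    """
    male = cell_table.index[cell_table["sex"] == "male"]
    sub = classified[classified["cell_id"].isin(male)]
    fx = biallelic_fraction_per_cell(sub, "chrX", min_snvs).dropna()
    f1 = biallelic_fraction_per_cell(sub, "chr1", min_snvs).dropna()
    days = cell_table["day"]
    by_day_x = {int(d): fx[days.reindex(fx.index) == d]
                for d in sorted(days.loc[male].unique())}
    by_day_1 = {int(d): f1[days.reindex(f1.index) == d]
                for d in sorted(days.loc[male].unique())}
    p = None
    if 3 in by_day_x and 4 in by_day_x and len(by_day_x[3]) >= 3 \
            and len(by_day_x[4]) >= 3:
        p = float(scipy.stats.mannwhitneyu(
            by_day_x[3], by_day_x[4], alternative="two-sided").pvalue)
    return {"chrX": by_day_x, "chr1": by_day_1, "p_e3_vs_e4": p}


def fisher_biallelic(n_biallelic_a: int, n_detected_a: int,
                     n_biallelic_b: int, n_detected_b: int) -> float:
    """Two-sided Fisher's exact p comparing biallelic proportions."""
    tab = [[n_biallelic_a, n_detected_a - n_biallelic_a],
           [n_biallelic_b, n_detected_b - n_biallelic_b]]
    return float(scipy.stats.fisher_exact(tab, alternative="two-sided")[1])
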