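"""Cell quality control, expressed-gene accounting and sex classification.

A cell passes QC when its best Spearman correlation to any other cell is at
least ``rho_min`` (default 0.63) — degraded or empty wells correlate with
nothing.  Sex is called per cell from the summed RPKM of Y-linked genes
(below 50 → female, above 100 → male, in between → unknown) and lifted to
the embryo by majority vote.  Spike-ins are excluded from the QC
correlations: they carry no biological signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import ExpressionDataset


def expressed_mask(dataset: ExpressionDataset, threshold: float = 1.0):
    """Boolean gene × cell expressed mask (RPKM ≥ threshold, inclusive)
    and per-cell expressed-gene counts."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = dataset.values >= threshold
    return mask, mask.sum(axis=0)


def max_spearman(dataset: ExpressionDataset, log: bool = True) -> pd.Series:
    """Per cell, the maximum Spearman correlation to any other cell.

    Computed on all non-spike-in genes; values are log2(RPKM+1) transformed
    by default (rank-based, so the transform only matters through ties).
    """
    bio = dataset.biological()
    if bio.n_cells < 2:
        raise ValueError("need at least two cells")
    x = bio.log_values() if log else bio.values
    ranks = scipy.stats.rankdata(x.to_numpy(), axis=0)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.sqrt((ranks ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    corr = (ranks / norms).T @ (ranks / norms)
    np.fill_diagonal(corr, -np.inf)
    return pd.Series(corr.max(axis=1), index=dataset.cells.index,
                     name="max_spearman")


def qc_filter(dataset: ExpressionDataset,
              rho_min: float = 0.63) -> ExpressionDataset:
    """Set ``qc_pass`` from the nearest-neighbour Spearman criterion.

    Idempotent once failing cells are dropped: the correlations of the
    remaining cells to each other are what already passed.
    """
    rho = max_spearman(dataset)
    out = dataset.copy()
    out.cells["qc_pass"] = (rho >= rho_min).to_numpy()
    out.cells["max_spearman"] = rho.to_numpy()
    return out


def passing(dataset: ExpressionDataset) -> ExpressionDataset:
    """Dataset restricted to QC-passing cells."""
    keep = dataset.cells.index[dataset.cells["qc_pass"].astype(bool)]
    return dataset.subset(cells=keep)


def classify_sex(dataset: ExpressionDataset, y_gene_ids=None,
                 low: float = 50.0, high: float = 100.0):
    """Per-cell and per-embryo sex from the Y-chromosome RPKM sum.

    Returns ``(dataset_with_sex, embryo_table)`` where the embryo table has
    columns ``sex`` (majority vote over classified cells) and ``conflict``
    (both sexes seen among the embryo's cells).
    """
    if y_gene_ids is None:
        y_gene_ids = dataset.genes.index[dataset.genes["chrom"] == "chrY"]
    y_gene_ids = [g for g in y_gene_ids if g in dataset.genes.index]
    if len(y_gene_ids) == 0:
        raise ValueError("no Y-chromosome genes in the annotation")
    ysum = dataset.values.loc[y_gene_ids].sum(axis=0)
    sex = pd.Series("unknown", index=dataset.cells.index, name="sex")
    sex[ysum < low] = "female"
    sex[ysum > high] = "male"

    out = dataset.copy()
    out.cells["sex"] = sex.to_numpy()
    out.cells["y_rpkm_sum"] = ysum.to_numpy()

    rows = []
    for embryo, members in out.cells.groupby("embryo_id").groups.items():
        calls = sex.loc[members]
        counts = calls[calls != "unknown"].value_counts()
        if counts.empty:
            embryo_sex = "unknown"
        else:
            embryo_sex = counts.idxmax()
        conflict = counts.get("female", 0) > 0 and counts.get("male", 0) > 0
        rows.append((embryo, embryo_sex, bool(conflict)))
    embryo_table = pd.DataFrame(rows, columns=["embryo_id", "sex",
                                               "conflict"])
    embryo_table = embryo_table.set_index("embryo_id")
    # cells inherit the embryo call where their own call is ambiguous
    out.cells["embryo_sex"] = embryo_table["sex"].reindex(
        out.cells["embryo_id"]).to_numpy()
    return out, embryo_table


def y_zga_summary(dataset: ExpressionDataset, ubiquitous_y_genes,
                  reference_days=(4, 5, 6, 7)):
    """Per-day male Y-gene expression, normalised to the E4–E7 median.

    The zygotic-genome-activation indicator: the per-cell mean RPKM over a
    set of ubiquitously expressed Y genes, divided by the median of that
    statistic over male cells of the reference stages.  Returns a dict with
    the per-day value Series and a two-sided Mann-Whitney p-value for E3
    versus E4 (set to None, with a warning, when E3 male cells are absent).
    """
    ubiquitous_y_genes = list(ubiquitous_y_genes)
    if not ubiquitous_y_genes:
        raise ValueError("empty Y gene set")
    male = dataset.cells.index[dataset.cells["sex"] == "male"]
    sub = dataset.subset(cells=male)
    if sub.cells["day"].nunique() < 2:
        raise ValueError("male cells needed at two or more days")
    stat = sub.values.loc[ubiquitous_y_genes].mean(axis=0)
    ref = stat[sub.cells["day"].isin(reference_days)]
    norm = stat / np.median(ref)
    by_day = {int(d): norm[sub.cells["day"] == d]
              for d in sorted(sub.cells["day"].unique())}
    p = None
    if 3 in by_day and 4 in by_day and len(by_day[3]) and len(by_day[4]):
        p = float(scipy.stats.mannwhitneyu(
            by_day[3], by_day[4], alternative="two-sided").pvalue)
    else:
        warnings.warn("no male E3 cells; skipping the E3-vs-E4 test")
    return {"normalized": norm, "by_day": by_day, "p_e3_vs_e4": p}
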