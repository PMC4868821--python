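"""Differential expression and lineage-specific gene statistics.

The workhorse test is a two-sided Wilcoxon rank-sum per gene on
log2(RPKM+1), converted to a signed z (sign from the pseudo-counted fold
change) so that per-lineage and per-day results can be combined with
Stouffer's method, Σz/√k.  Multiple testing is controlled with
Benjamini–Hochberg at FDR ≤ 5%.  Genes expressed (RPKM ≥ 1) in fewer than
10% of both groups are excluded before testing to avoid zero-inflation
artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

_PMIN = 1e-300


def de_two_groups(dataset: ExpressionDataset, cells_a, cells_b,
                  expressed_threshold: float = 1.0,
                  min_expressed_frac: float = 0.1) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression, group A versus group B.

    Returns a per-gene table with columns ``z`` (signed normal quantile of
    the two-sided p, sign from the fold change), ``log2fc`` =
    log2((mean_A+1)/(mean_B+1)), ``p`` and ``fdr``.  Swapping the groups
    negates z and log2fc.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    bio = dataset.biological()
    va = bio.values[cells_a].to_numpy()
    vb = bio.values[cells_b].to_numpy()
    frac_a = (va >= expressed_threshold).mean(axis=1)
    frac_b = (vb >= expressed_threshold).mean(axis=1)
    keep = (frac_a >= min_expressed_frac) | (frac_b >= min_expressed_frac)
    genes = bio.values.index[keep]
    la = np.log2(va[keep] + 1.0)
    lb = np.log2(vb[keep] + 1.0)
    res = scipy.stats.mannwhitneyu(la, lb, axis=1,
                                   alternative="two-sided",
                                   method="asymptotic")
    p = np.clip(res.pvalue, _PMIN, 1.0)
    log2fc = np.log2((va[keep].mean(axis=1) + 1.0)
                     / (vb[keep].mean(axis=1) + 1.0))
    sign = np.sign(log2fc)
    sign[sign == 0] = 1.0
    z = sign * scipy.stats.norm.isf(p / 2.0)
    fdr = bh_fdr(p)
    return pd.DataFrame({"z": z, "log2fc": log2fc, "p": p, "fdr": fdr},
                        index=genes)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def stouffer(zs) -> float:
    """Combine signed z-scores: Σz/√k."""
    zs = np.asarray(list(zs), float)
    if zs.size == 0:
        raise ValueError("empty z-score list")
    if not np.all(np.isfinite(zs)):
        raise ValueError("non-finite z-score")
    return float(zs.sum() / np.sqrt(zs.size))


def stouffer_frame(z_frames: list) -> pd.DataFrame:
    """Row-wise Stouffer combination of aligned per-gene z tables.

    Only genes present in every input are combined; returns ``z``, ``p``
    (two-sided) and ``fdr``.
    """
    common = z_frames[0].index
    for f in z_frames[1:]:
        common = common.intersection(f.index)
    z = sum(f.loc[common, "z"].to_numpy() for f in z_frames)
    z = z / np.sqrt(len(z_frames))
    p = np.clip(2.0 * scipy.stats.norm.sf(np.abs(z)), _PMIN, 1.0)
    return pd.DataFrame({"z": z, "p": p, "fdr": bh_fdr(p)}, index=common)


def lineage_specific(dataset: ExpressionDataset, calls: pd.DataFrame,
                     day: int, lineages=("TE", "EPI", "PE"),
                     fdr_level: float = 0.05) -> dict:
    """Within-day lineage-specific gene rankings.

    For each lineage L the two contrasts L-vs-M and L-vs-N are combined
    with Stouffer's method; positive combined z means up in L.  Returns
    {lineage: DataFrame(z, p, fdr, significant, rank)}; the stored
    pairwise contrasts sit under the ``"contrasts"`` key for auditability.
    """
    day_cells = dataset.cells.index[dataset.cells["day"] == day]
    groups = {}
    for lin in lineages:
        members = day_cells[calls.loc[day_cells, "lineage"] == lin]
        if len(members) < 3:
            raise ValueError(f"lineage {lin} missing (or <3 cells) "
                             f"at day {day}")
        groups[lin] = list(members)
    contrasts = {}
    for lin in lineages:
        for other in lineages:
            if lin < other:
                contrasts[(lin, other)] = de_two_groups(
                    dataset, groups[lin], groups[other])
    out = {"contrasts": contrasts}
    for lin in lineages:
        frames = []
        for other in lineages:
            if other == lin:
                continue
            if (lin, other) in contrasts:
                frames.append(contrasts[(lin, other)])
            else:
                flipped = contrasts[(other, lin)].copy()
                flipped[["z", "log2fc"]] *= -1.0
                frames.append(flipped)
        combined = stouffer_frame(frames)
        # "specific to L" is the positive side: up in L against both others
        combined["significant"] = (combined["fdr"] <= fdr_level) \
            & (combined["z"] > 0)
        combined = combined.sort_values("z", ascending=False)
        combined["rank"] = np.arange(1, len(combined) + 1)
        out[lin] = combined
    return out


def maintained_genes(per_day_rankings: dict, lineage: str,
                     fdr_level: float = 0.05) -> pd.DataFrame:
    """Across-day maintained lineage specificity.

    Stouffer-combines one lineage's within-day combined z over the days
    given (genes missing on any day are excluded); flags FDR ≤ 5% and
    ranks descending by combined z.
    """
    frames = [per_day_rankings[day][lineage] for day in
              sorted(per_day_rankings)]
    combined = stouffer_frame(frames)
    combined["significant"] = (combined["fdr"] <= fdr_level) \
        & (combined["z"] > 0)
    combined = combined.sort_values("z", ascending=False)
    combined["rank"] = np.arange(1, len(combined) + 1)
    return combined


def embryo_variability_regression(dataset: ExpressionDataset,
                                  embryo_pseudotime: pd.Series,
                                  min_cells: int = 3,
                                  expressed_threshold: float = 1.0
                                  ) -> pd.DataFrame:
    """Within-embryo expression variability regressed on embryo time.

    The variability score of a gene in an embryo is the squared
    coefficient of variation of log2(RPKM+1) across the embryo's cells,
    defined only in embryos where the gene is expressed (mean RPKM ≥
    threshold) — CV² of a silent gene is dominated by the near-zero mean
    and carries no signal.  The score is regressed (OLS) on embryo
    pseudo-time over the embryos where it is defined; ``peak_time`` is
    the embryo time of maximum variability.  Embryos with fewer than
    ``min_cells`` cells are skipped.
    """
    bio = dataset.biological()
    logv = bio.log_values().to_numpy()
    raw = bio.values.to_numpy()
    embryos, times, scores = [], [], []
    for embryo, members in bio.cells.groupby("embryo_id").groups.items():
        if embryo not in embryo_pseudotime.index:
            continue
        idx = bio.cells.index.get_indexer(members)
        if len(idx) < min_cells:
            continue
        sub = logv[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(m > 0, v / m ** 2, 0.0)
        cv2[raw[:, idx].mean(axis=1) < expressed_threshold] = np.nan
        embryos.append(embryo)
        times.append(float(embryo_pseudotime[embryo]))
        scores.append(cv2)
    if len(embryos) < 3:
        raise ValueError("need at least 3 embryos with enough cells")
    t = np.asarray(times)
    s = np.vstack(scores).T                      # genes × embryos
    defined = ~np.isnan(s)
    n_def = defined.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = (np.where(defined, t[None, :], 0.0).sum(axis=1)
                  / np.maximum(n_def, 1))
        s_mean = np.nansum(s, axis=1) / np.maximum(n_def, 1)
        tc = np.where(defined, t[None, :] - t_mean[:, None], 0.0)
        sc = np.where(defined, s - s_mean[:, None], 0.0)
        slope = (tc * sc).sum(axis=1) / (tc ** 2).sum(axis=1)
    slope[n_def < 3] = np.nan
    masked = np.where(defined, s, -np.inf)
    peak_time = np.where(n_def > 0, t[np.argmax(masked, axis=1)], np.nan)
    return pd.DataFrame({"slope": slope, "peak_time": peak_time,
                         "n_embryos": n_def}, index=bio.values.index)


def stage_gene_correlations(dataset: ExpressionDataset, genes,
                            stage_partition: dict,
                            cut_height: float = 0.7,
                            gene_groups: pd.Series | None = None) -> dict:
    """Per-stage gene × gene Pearson matrices and hierarchical modules.

    ``stage_partition`` maps stage name → list of cell IDs (each stage
    needs ≥3 cells).  Correlations are Pearson on log2(RPKM+1); genes
    constant within a stage get missing correlations.  Modules come from
    average-linkage clustering of 1−r cut at ``cut_height``; when
    ``gene_groups`` (e.g. lineage/wave membership) is given each module is
    named after its dominant group.
    """
    sch = scipy.cluster.hierarchy
    genes = list(genes)
    out = {}
    for stage, cells in stage_partition.items():
        cells = list(cells)
        if len(cells) < 3:
            raise ValueError(f"stage {stage!r} has fewer than 3 cells")
        x = dataset.log_values(genes=genes, cells=cells).to_numpy()
        sd = x.std(axis=1)
        corr = np.full((len(genes), len(genes)), np.nan)
        ok = sd > 0
        if ok.sum() >= 2:
            sub = np.corrcoef(x[ok])
            corr[np.ix_(ok, ok)] = sub
        corr_df = pd.DataFrame(corr, index=genes, columns=genes)

        modules = pd.Series("unassigned", index=pd.Index(genes))
        if ok.sum() >= 3:
            d = 1.0 - corr[np.ix_(ok, ok)]
            np.fill_diagonal(d, 0.0)
            condensed = scipy.spatial.distance.squareform(d, checks=False)
            link = sch.linkage(condensed, method="average")
            labels = sch.fcluster(link, t=cut_height, criterion="distance")
            named = {}
            for lab in np.unique(labels):
                member_genes = np.asarray(genes)[ok][labels == lab]
                if gene_groups is not None:
                    dominant = (gene_groups.reindex(member_genes)
                                .mode().iloc[0])
                    named[lab] = f"{dominant}.{lab}"
                else:
                    named[lab] = f"module{lab}"
            modules.loc[np.asarray(genes)[ok]] = [named[l] for l in labels]
        out[stage] = {"corr": corr_df, "modules": modules}
    return out


def sex_de(dataset: ExpressionDataset, day: int,
           lineage: str | None = None,
           calls: pd.DataFrame | None = None,
           n_bootstrap: int = 100, seed: int = 0) -> dict:
    """Female-vs-male differential expression within a day (and lineage).

    Returns the DE table, counts of significant genes by chromosome class
    (chrX / chrY / autosome), and the percentage of genes with
    female:male fold change ≥2 together with its bootstrap SD over cells
    (B resamples).
    """
    cells = dataset.cells
    stratum = cells.index[cells["day"] == day]
    if lineage is not None:
        if calls is None:
            raise ValueError("lineage stratification needs lineage calls")
        stratum = stratum[calls.loc[stratum, "lineage"] == lineage]
    female = [c for c in stratum if cells.loc[c, "sex"] == "female"]
    male = [c for c in stratum if cells.loc[c, "sex"] == "male"]
    if not female or not male:
        raise ValueError("both sexes must be present in the stratum")
    de = de_two_groups(dataset, female, male)

    chrom = dataset.genes["chrom"].reindex(de.index)
    cls = pd.Series(np.where(chrom == "chrX", "chrX",
                             np.where(chrom == "chrY", "chrY", "autosome")),
                    index=de.index)
    sig = de["fdr"] <= 0.05
    counts = cls[sig].value_counts().reindex(
        ["chrX", "chrY", "autosome"], fill_value=0)

    bio = dataset.biological()
    vf = bio.values[female].to_numpy()
    vm = bio.values[male].to_numpy()
    tested = bio.values.index.get_indexer(de.index)
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        fi = rng.integers(0, vf.shape[1], vf.shape[1])
        mi = rng.integers(0, vm.shape[1], vm.shape[1])
        fc = (vf[np.ix_(tested, fi)].mean(axis=1) + 1.0) / \
             (vm[np.ix_(tested, mi)].mean(axis=1) + 1.0)
        fracs[b] = 100.0 * (fc >= 2.0).mean()
    fc_obs = (vf[tested].mean(axis=1) + 1.0) / (vm[tested].mean(axis=1) + 1.0)
    return {"de": de, "chrom_class": cls, "sig_counts": counts,
            "pct_fc2": 100.0 * float((fc_obs >= 2.0).mean()),
            "pct_fc2_sd": float(fracs.std(ddof=1))}
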