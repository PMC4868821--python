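"""Hierarchical per-day lineage classification.

The blastocyst lineages are called in three nested steps, separately per
embryonic day: (1) embryos whose mean pseudo-time lies below the
pre-lineage gate (default 12.5, i.e. younger than mid-E5) are called
``pre``; (2) the remaining cells of the day are split ICM vs TE by
k-medoids (PAM) on the first two principal components of the day's 250
most variable genes; (3) ICM cells are split EPI vs PE the same way, and
TE cells of E6/E7 are split polar vs mural.  A split is accepted only when
its mean silhouette (computed on log-expression distances over the
clustering gene set) reaches the no-split gate — unstructured cells stay
unresolved, which is exactly the behaviour expected of pre-blastocyst
stages.

Cluster identities are named by marker panels: the per-cell score is the
mean over panel genes of weight × z-scored log expression with weights −1
and +1 for the two sets, and the cluster with the higher mean score takes
the +1 name.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.spatial.distance
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datasets import ExpressionDataset
from .variability import NoiseFit, top_variable_genes, variability_scores

# Default marker panels (editable; names follow the field's convention and
# match the simulator's program genes).
ICM_TE_PANEL = {
    "minus": ["SOX2", "NANOG", "PDGFRA", "GATA4"],       # ICM
    "plus": ["GATA2", "GATA3", "DAB2", "PTGES"],         # TE
    "minus_name": "ICM", "plus_name": "TE",
}
EPI_PE_PANEL = {
    "minus": ["NANOG", "SOX2", "PRDM14", "TDGF1", "GDF3"],   # EPI
    "plus": ["GATA4", "HNF1B", "PDGFRA", "COL4A1"],          # PE
    "minus_name": "EPI", "plus_name": "PE",
}
POLAR_GENES = ["CCR7", "CYP19A1", "DLX5", "ERVFRD-1", "GCM1", "GREM2",
               "MUC15", "OVOL1"]


@dataclasses.dataclass
class MarkerPanel:
    """Two disjoint marker sets with weights −1 (minus) and +1 (plus)."""
    minus: list
    plus: list
    minus_name: str
    plus_name: str

    def __post_init__(self):
        if set(self.minus) & set(self.plus):
            raise ValueError("marker sets must be disjoint")

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(minus=list(d["minus"]), plus=list(d["plus"]),
                   minus_name=d["minus_name"], plus_name=d["plus_name"])

    def swapped(self) -> "MarkerPanel":
        """Swap the ±1 weights (gene sets trade places, names keep their
        weight slot), which flips every labelling decision."""
        return MarkerPanel(minus=self.plus, plus=self.minus,
                           minus_name=self.minus_name,
                           plus_name=self.plus_name)


# ---------------------------------------------------------------------------
# PAM (k-medoids) with deterministic BUILD initialisation
# ---------------------------------------------------------------------------

def pam_cluster(x: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on Euclidean distances.

    Medoids are initialised with the greedy BUILD step and refined by
    best-improvement SWAP, so the result is deterministic — no seed
    sensitivity in the lineage calls.
    """
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError("fewer points than clusters")
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x))
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gain = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi in range(k):
            others = np.setdiff1d(np.arange(n), medoids)
            for cand in others:
                trial = medoids.copy()
                trial[mi] = cand
                new_cost = dist[:, trial].min(axis=1).sum()
                if cost - new_cost > best[0] + 1e-12:
                    best = (cost - new_cost, trial)
        if best[1] is None:
            break
        medoids = best[1]
    return np.argmin(dist[:, medoids], axis=1)


def cluster_two(dataset: ExpressionDataset, cells, genes, n_pcs: int = 2,
                k: int = 2):
    """PAM split in the PCA subspace of log expression over ``genes``.

    Returns ``(labels, silhouette)``: integer cluster labels per cell and
    the mean silhouette width of the split, computed on the full
    log-expression distances (the split-quality gate).
    """
    cells = list(cells)
    if k < 2:
        raise ValueError("k must be at least 2 (a 1-cluster silhouette is "
                         "undefined)")
    if len(cells) < 2 * k:
        raise ValueError(f"need at least {2 * k} cells for a {k}-way split")
    x = dataset.log_values(genes=list(genes), cells=cells).to_numpy().T
    n_pcs = min(n_pcs, min(x.shape) - 1)
    scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
    labels = pam_cluster(scores, k)
    sil = float(silhouette_score(x, labels)) if len(set(labels)) > 1 else 0.0
    return pd.Series(labels, index=pd.Index(cells, name="cell_id")), sil


def marker_score(dataset: ExpressionDataset, cells,
                 panel: MarkerPanel) -> pd.Series:
    """Weighted mean of z-scored log expression over the panel genes."""
    genes = panel.minus + panel.plus
    missing = [g for g in genes if g not in dataset.genes.index]
    if missing:
        raise ValueError(f"marker genes absent from dataset: {missing}")
    logv = dataset.log_values(genes=genes, cells=list(cells))
    arr = logv.to_numpy()
    sd = arr.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    weights = np.array([-1.0] * len(panel.minus) + [1.0] * len(panel.plus))
    return pd.Series((weights[:, None] * z).mean(axis=0),
                     index=logv.columns, name="marker_score")


def label_clusters(labels: pd.Series, dataset: ExpressionDataset,
                   panel: MarkerPanel):
    """Name the two clusters by their mean marker score.

    The cluster with the higher mean score gets the +1-set name.  Returns
    ``(named, scores)`` with ``named`` mapping each cell to a lineage name.
    """
    if labels.nunique() != 2 or (labels.value_counts() == 0).any():
        raise ValueError("need exactly two non-empty clusters")
    scores = marker_score(dataset, labels.index, panel)
    means = scores.groupby(labels).mean()
    plus_cluster = means.idxmax()
    named = labels.map(lambda c: panel.plus_name if c == plus_cluster
                       else panel.minus_name)
    return named, scores


def polar_score(dataset: ExpressionDataset, te_cells,
                polar_genes) -> pd.Series:
    """Per-cell mean of per-gene z-scores over the polar gene set."""
    polar_genes = [g for g in polar_genes if g in dataset.genes.index]
    if not polar_genes:
        raise ValueError("empty polar gene list")
    logv = dataset.log_values(genes=polar_genes, cells=list(te_cells))
    arr = logv.to_numpy()
    sd = arr.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(z.mean(axis=0), index=logv.columns, name="polar_score")


# ---------------------------------------------------------------------------
# the hierarchical caller
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LineageCallConfig:
    pre_lineage_threshold: float = 12.5    # embryo pseudo-time gate (units of 2.5/day)
    n_top_genes: int = 250
    n_top_genes_subpop: int = 50           # polar/mural split within TE
    min_subpop_cells: int = 12
    n_pcs: int = 2
    silhouette_gate: float = 0.2           # refuse splits below this (null-calibrated)
    icm_te_panel: dict = dataclasses.field(
        default_factory=lambda: dict(ICM_TE_PANEL))
    epi_pe_panel: dict = dataclasses.field(
        default_factory=lambda: dict(EPI_PE_PANEL))
    polar_genes: list = dataclasses.field(
        default_factory=lambda: list(POLAR_GENES))


def call_lineages(dataset: ExpressionDataset, pseudotime, fit: NoiseFit,
                  config: LineageCallConfig | None = None) -> pd.DataFrame:
    """Per-cell lineage table: pre / TE / ICM→(EPI, PE) and polar/mural.

    ``pseudotime`` is a PseudotimeAssignment (or anything with
    ``embryo_lambda``).  Days 3–4 are always pre; at days 5–7 whole embryos
    below the pseudo-time gate are pre, the rest are split hierarchically.
    Columns: lineage, te_subpop, silhouette, marker_score.
    """
    if pseudotime is None:
        raise ValueError("pseudotime assignment is required")
    config = config or LineageCallConfig()
    embryo_lambda = pseudotime.embryo_lambda
    cells = dataset.cells
    out = pd.DataFrame({
        "lineage": "pre", "te_subpop": "NA",
        "silhouette": np.nan, "marker_score": np.nan,
    }, index=cells.index)

    icm_te_panel = MarkerPanel.from_dict(config.icm_te_panel)
    epi_pe_panel = MarkerPanel.from_dict(config.epi_pe_panel)

    for day in sorted(cells["day"].unique()):
        if day < 5:
            continue
        day_cells = cells.index[cells["day"] == day]
        lam = embryo_lambda.reindex(cells.loc[day_cells, "embryo_id"])
        mature = day_cells[(lam >= config.pre_lineage_threshold).to_numpy()]
        if len(mature) < 4:
            continue
        day_ds = dataset.subset(cells=mature)
        genes = _day_top_genes(day_ds, fit, config.n_top_genes)
        labels, sil = cluster_two(dataset, mature, genes,
                                  n_pcs=config.n_pcs)
        out.loc[mature, "silhouette"] = sil
        if sil < config.silhouette_gate:
            out.loc[mature, "lineage"] = "ICM-unresolved"
            continue
        named, scores = label_clusters(labels, dataset, icm_te_panel)
        out.loc[mature, "lineage"] = named
        out.loc[mature, "marker_score"] = scores

        icm = mature[(named == "ICM").to_numpy()]
        if len(icm) >= 4:
            icm_ds = dataset.subset(cells=icm)
            icm_genes = _day_top_genes(icm_ds, fit, config.n_top_genes)
            ilabels, isil = cluster_two(dataset, icm, icm_genes,
                                        n_pcs=config.n_pcs)
            out.loc[icm, "silhouette"] = isil
            if isil >= config.silhouette_gate:
                inames, iscores = label_clusters(ilabels, dataset,
                                                 epi_pe_panel)
                out.loc[icm, "lineage"] = inames
                out.loc[icm, "marker_score"] = iscores
            else:
                out.loc[icm, "lineage"] = "ICM-unresolved"

        te = mature[(named == "TE").to_numpy()]
        if day >= 6 and len(te) >= config.min_subpop_cells:
            te_ds = dataset.subset(cells=te)
            te_genes = _day_top_genes(te_ds, fit,
                                      config.n_top_genes_subpop)
            tlabels, tsil = cluster_two(dataset, te, te_genes,
                                        n_pcs=config.n_pcs)
            if tsil >= config.silhouette_gate:
                pscore = polar_score(dataset, te, config.polar_genes)
                means = pscore.groupby(tlabels).mean()
                polar_cluster = means.idxmax()
                out.loc[te, "te_subpop"] = [
                    "polar" if c == polar_cluster else "mural"
                    for c in tlabels]
    return out


def _day_top_genes(day_ds: ExpressionDataset, fit: NoiseFit, n: int):
    scores = variability_scores(day_ds, fit)
    return top_variable_genes(scores, min(n, len(scores)))


def lineage_counts(calls: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Cells per lineage per embryonic day (the summary-table layout)."""
    df = calls.join(cells[["day"]])
    return (df.groupby(["day", "lineage"]).size()
            .unstack(fill_value=0))
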