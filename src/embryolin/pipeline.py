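"""Config-driven orchestration of the full analysis.

``run`` executes every stage on one dataset — simulate (optional) → QC and
sex → technical-noise fit and variable genes → embedding and pseudo-time →
hierarchical lineage calls → lineage-specific and maintained genes →
segregation scoring → X-dosage statistics → allelic statistics — and
writes per-stage TSV tables plus a JSON summary.  All outputs are plain
text, so reruns with the same seed are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, diffexpr, lineage, qc, segregation, xdosage
from .datasets import (ExpressionDataset, read_allele_table, read_dataset,
                       write_allele_table, write_dataset)
from .pseudotime import assign_pseudotime
from .simulate import SimConfig, simulate_experiment
from .variability import (embed_2d, fit_noise_from_dataset,
                          top_variable_genes, variability_scores)

log = logging.getLogger("embryolin")


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline thresholds in one schema-validated place.

    Defaults reproduce the study-parameterised run: QC at ρ ≥ 0.63,
    sex thresholds 50/100, 500 global / 250 per-day variable genes,
    pre-lineage gate 12.5, null-calibrated silhouette gate 0.2, FDR 5%,
    25-gene moving
    window and the allelic thresholds (3 reads detected, minor ≥2 reads
    and ≥10%, ≥25 chrX SNVs per cell).
    """

    # inputs: either simulate or load
    simulate: bool = True
    sim: dict = dataclasses.field(default_factory=dict)
    matrix_path: str | None = None
    genes_path: str | None = None
    cells_path: str | None = None
    allele_path: str | None = None
    # stage parameters
    rho_min: float = 0.63
    sex_low: float = 50.0
    sex_high: float = 100.0
    expressed_threshold: float = 1.0
    cv_bio: float = 0.5
    n_top_genes_global: int = 500
    n_top_genes_day: int = 250
    embedding: str = "diffusion"
    tsne_perplexity: float = 30.0
    pre_lineage_threshold: float = 12.5
    silhouette_gate: float = 0.2
    n_pcs: int = 2
    fdr_level: float = 0.05
    window: int = 25
    min_reads: int = 3
    minor_min_reads: int = 2
    minor_min_frac: float = 0.1
    min_snvs: int = 25
    seed: int = 0
    # stage toggles
    stages: tuple = ("qc", "pseudotime", "lineage", "genes", "segregation",
                     "dosage", "allelic")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw = dict(raw, stages=tuple(raw["stages"]))
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the JSON-ready summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(),
                     "seed": config.seed}
    truth = None

    try:
        stage = "input"
        if config.simulate:
            sim_config = SimConfig(**config.sim)
            if "seed" not in config.sim:
                sim_config.seed = config.seed
            dataset, allele_table, truth = simulate_experiment(sim_config)
            write_dataset(dataset, outdir / "matrix.tsv",
                          outdir / "genes.tsv", outdir / "cells.tsv")
            write_allele_table(allele_table, outdir / "alleles.tsv")
        else:
            for path in (config.matrix_path, config.genes_path,
                         config.cells_path):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"missing input {path}")
            dataset = read_dataset(config.matrix_path, config.genes_path,
                                   config.cells_path)
            allele_table = (read_allele_table(config.allele_path)
                            if config.allele_path else None)
        summary["n_cells_input"] = dataset.n_cells

        stage = "qc"
        if "qc" in config.stages:
            dataset = qc.qc_filter(dataset, rho_min=config.rho_min)
            dataset, embryo_sex = qc.classify_sex(
                dataset, low=config.sex_low, high=config.sex_high)
            dataset = qc.passing(dataset)
            embryo_sex.to_csv(outdir / "embryo_sex.tsv", sep="\t")
            _, n_expressed = qc.expressed_mask(
                dataset, config.expressed_threshold)
            summary["n_cells_qc"] = dataset.n_cells
            summary["mean_expressed_genes"] = float(n_expressed.mean())

        stage = "noise_fit"
        fit = fit_noise_from_dataset(dataset, cv_bio=config.cv_bio)
        scores = variability_scores(dataset, fit)
        scores.to_csv(outdir / "variability.tsv", sep="\t")
        summary["noise_fit"] = {"a1": fit.a1, "alpha0": fit.alpha0}
        global_genes = top_variable_genes(
            scores, min(config.n_top_genes_global, len(scores)))

        stage = "pseudotime"
        pt = None
        if "pseudotime" in config.stages:
            coords = embed_2d(dataset, global_genes,
                              method=config.embedding, seed=config.seed,
                              perplexity=config.tsne_perplexity)
            pt = assign_pseudotime(coords, dataset.cells["day"],
                                   dataset.cells["embryo_id"])
            pd.DataFrame({"pseudotime": pt.cell_lambda}).to_csv(
                outdir / "pseudotime.tsv", sep="\t")
            pt.embryo_lambda.to_csv(outdir / "embryo_pseudotime.tsv",
                                    sep="\t")

        stage = "lineage"
        calls = None
        if "lineage" in config.stages and pt is not None:
            lcfg = lineage.LineageCallConfig(
                pre_lineage_threshold=config.pre_lineage_threshold,
                n_top_genes=config.n_top_genes_day,
                n_pcs=config.n_pcs,
                silhouette_gate=config.silhouette_gate)
            calls = lineage.call_lineages(dataset, pt, fit, lcfg)
            calls.to_csv(outdir / "lineage_calls.tsv", sep="\t")
            counts = lineage.lineage_counts(calls, dataset.cells)
            counts.to_csv(outdir / "lineage_counts.tsv", sep="\t")
            summary["lineage_counts"] = {
                str(day): {str(k): int(v) for k, v in row.items()}
                for day, row in counts.iterrows()}

        stage = "genes"
        maintained = {}
        if "genes" in config.stages and calls is not None:
            per_day = {}
            for day in (5, 6, 7):
                day_cells = dataset.cells["day"] == day
                if not day_cells.any():
                    continue
                have = calls.loc[day_cells.to_numpy(), "lineage"]
                if not all((have == lin).sum() >= 3
                           for lin in ("TE", "EPI", "PE")):
                    continue
                per_day[day] = diffexpr.lineage_specific(
                    dataset, calls, day, fdr_level=config.fdr_level)
            summary["lineage_gene_counts"] = {
                str(day): {lin: int(res[lin]["significant"].sum())
                           for lin in ("TE", "EPI", "PE")}
                for day, res in per_day.items()}
            if len(per_day) == 3:
                for lin in ("TE", "EPI", "PE"):
                    maintained[lin] = diffexpr.maintained_genes(
                        per_day, lin, fdr_level=config.fdr_level)
                    maintained[lin].to_csv(
                        outdir / f"maintained_{lin}.tsv", sep="\t")
                summary["maintained_counts"] = {
                    lin: int(maintained[lin]["significant"].sum())
                    for lin in maintained}

        stage = "segregation"
        if "segregation" in config.stages and calls is not None \
                and maintained:
            seg_genes = []
            for lin in maintained:
                m = maintained[lin]
                seg_genes += list(m.index[m["significant"]][:100])
            if len(seg_genes) >= 10:
                coords3 = segregation.diffusion_embedding(
                    dataset, seg_genes, n_components=3)
                matured = calls["lineage"].where(
                    calls["lineage"].isin(["TE", "EPI", "PE"]))
                icm_te = matured.replace({"EPI": "ICM", "PE": "ICM"})
                try:
                    _, dist = segregation.fit_segregation_surface(
                        coords3[["DC1", "DC2"]], icm_te.dropna())
                    prof = segregation.segregation_vs_time(
                        dist, dataset.cells["embryo_id"], pt.embryo_lambda)
                    prof["curve"].to_csv(outdir / "segregation.tsv",
                                         sep="\t", index=False)
                    summary["segregation_changepoint"] = prof["changepoint"]
                except ValueError as err:
                    log.warning("segregation skipped: %s", err)

        stage = "dosage"
        if "dosage" in config.stages:
            dosage = {}
            for day in sorted(dataset.cells["day"].unique()):
                try:
                    res = xdosage.fm_ratio_per_gene(
                        dataset, day,
                        expressed_threshold=config.expressed_threshold)
                except ValueError:
                    continue
                dosage[str(day)] = {
                    "chrX_median": res["chrX_median"],
                    "autosome_median": res["autosome_median"]}
            summary["fm_ratio_by_day"] = dosage

        stage = "allelic"
        if "allelic" in config.stages and allele_table is not None:
            classified = allelic.classify_table(
                allele_table, min_reads=config.min_reads,
                minor_min_reads=config.minor_min_reads,
                minor_min_frac=config.minor_min_frac)
            keep = classified["cell_id"].isin(dataset.cells.index)
            classified = classified[keep]
            rel = allelic.relative_biallelic_ratio(
                classified, min_snvs=config.min_snvs)
            rel.to_csv(outdir / "relative_biallelic.tsv", sep="\t")
            days = dataset.cells["day"].reindex(rel.index)
            sexes = dataset.cells["sex"].reindex(rel.index)
            summary["relative_biallelic_median_female"] = {
                str(int(d)): float(np.nanmedian(
                    rel[(days == d) & (sexes == "female")]))
                for d in sorted(days.dropna().unique())
                if ((days == d) & (sexes == "female")).sum() > 0}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    summary_json = json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(summary_json + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
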