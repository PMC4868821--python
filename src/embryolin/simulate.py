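"""Allele-resolved synthetic preimplantation scRNA-seq generator.

The generator emulates a Smart-seq2-like RPKM matrix over embryonic days
E3–E7 together with a per-cell, per-SNV allele read-count table and the
ground truth needed to test every downstream stage:

* three lineage programs (TE, EPI, PE) whose genes switch on in activation
  waves (early/mid/late) after a commitment day, preceded by an uncommitted
  state in which cells co-express the early genes of all three programs at a
  configurable fraction of the committed level;
* temporal genes rising or decaying smoothly with developmental time (the
  signal pseudo-time inference recovers), including maternal-decay genes;
* ERCC-like spike-ins with purely technical noise, CV² = a1/μ + α0;
* sex-linked structure: Y genes expressed only in male cells (reduced at E3
  where zygotic genome activation is incomplete), XIST/XACT programs, and
  chrX genes whose female output follows one of three dosage regimes —
  two active X chromosomes, biallelic dampening, or whole-cell X
  inactivation;
* heterozygous SNV read counts drawn with beta-binomial overdispersion
  around the per-cell allele-activity ratio, with optional maternal
  transcript carryover making male E3 chrX reads partially biallelic.

Expression noise is Gamma-Poisson (negative binomial) on the expected RPKM
followed by mean-dependent logistic dropout, which reproduces the familiar
mean–CV² shape without modelling reads.  With a fixed seed the output is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import ALLELE_COLUMNS, ExpressionDataset

DOSAGE_MODES = ("two_active", "dampening", "xci")

# Per-allele dampening factor by day; 0.55 at E7 leaves a female:male total
# of 2*0.55 = 1.1, i.e. most of the way to full compensation.
DEFAULT_DAMPENING_SCHEDULE = {3: 1.0, 4: 1.0, 5: 0.85, 6: 0.7, 7: 0.55}
# Fraction of female cells with one whole X silenced, by day.
DEFAULT_XCI_SCHEDULE = {3: 0.0, 4: 0.0, 5: 0.2, 6: 0.45, 7: 0.6}

# First genes of each program carry field-standard marker names so that the
# default marker panels of the lineage caller apply to simulated data.
TE_MARKERS = ["GATA2", "GATA3", "DAB2", "PTGES", "EMP2", "TGFBR3", "PDGFA",
              "CDX2", "CLDN4", "CLDN10", "SLC2A1"]
EPI_MARKERS = ["NANOG", "SOX2", "PRDM14", "TDGF1", "GDF3", "DPPA5", "ESRG",
               "KLF17", "ARGFX", "NODAL", "DPPA2"]
PE_MARKERS = ["GATA4", "HNF1B", "PDGFRA", "COL4A1", "LINC00261", "FRZB",
              "AMOTL1", "DPP4", "FN1", "FOXA2"]
POLAR_MARKERS = ["CCR7", "CYP19A1", "DLX5", "ERVFRD-1", "GCM1", "GREM2",
                 "MUC15", "OVOL1"]
Y_MARKERS = ["RPS4Y1", "DDX3Y", "EIF1AY", "KDM5D", "UTY", "USP9Y", "ZFY",
             "TMSB4Y", "NLGN4Y", "RPS4Y2", "TXLNGY", "PRKY"]

LINEAGES = ("TE", "EPI", "PE")
WAVE_ONSET = {"early": 4.0, "mid": 5.0, "late": 6.0}


class SimConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults produce a five-day experiment with four embryos per day, three
    lineage programs of 100 genes each committing at E5, spike-ins with
    technical noise (a1, α0) = (4.0, 0.05), and two active X chromosomes in
    females.
    """

    n_embryos_per_day: dict = dataclasses.field(
        default_factory=lambda: {3: 4, 4: 4, 5: 8, 6: 8, 7: 8})
    cells_per_embryo: tuple = (10, 14)         # inclusive range
    n_genes: int = 1600                        # biological genes, programs included
    n_spikeins: int = 60
    lineage_gene_counts: dict = dataclasses.field(
        default_factory=lambda: {"TE": 100, "EPI": 100, "PE": 100})
    wave_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)   # early/mid/late
    n_temporal_genes: int = 250                # half rising, half maternal decay
    n_polar_genes: int = 40
    n_x_genes: int = 120                       # chrX genes beside XIST/XACT
    coexpression_level: float = 0.5            # uncommitted fraction of committed level
    te_leak_level: float = 0.25                # TE-gene level in committed non-TE cells
    # EPI<->PE cross-expression within the ICM: the sibling program stays
    # partially expressed so the ICM-TE axis remains the dominant split
    icm_cross_schedule: dict = dataclasses.field(
        default_factory=lambda: {5: 0.2, 6: 0.2, 7: 0.2})
    commit_day: float = 5.0
    dosage_mode: str = "two_active"
    dampening_schedule: Optional[dict] = None
    xci_schedule: Optional[dict] = None
    burst_dispersion: float = 0.3              # baseline biological CV (housekeeping)
    program_cv: float = 0.5                    # added biological CV of lineage/polar genes
    temporal_cv: float = 0.4                   # added biological CV of stage genes
    dropout_shape: tuple = (0.7, 0.5)          # logistic midpoint/scale on log2(mu+1)
    tech_noise: tuple = (4.0, 0.05)            # (a1, alpha0) spike-in CV^2 model
    het_snv_per_gene: int = 1
    snv_coverage: float = 0.3                  # expected SNV reads per RPKM unit
    allele_concentration: float = 40.0         # beta-binomial concentration
    maternal_carryover: float = 0.3            # minor-allele fraction, male chrX at E3
    n_x0_embryos: int = 0                      # female embryos with a single X
    seed: int = 0

    def validate(self) -> None:
        if self.dosage_mode not in DOSAGE_MODES:
            raise SimConfigError(f"unknown dosage_mode {self.dosage_mode!r}")
        if self.dosage_mode == "xci" and self.dampening_schedule is not None:
            raise SimConfigError(
                "dampening_schedule given with dosage_mode='xci'")
        if self.dosage_mode == "dampening" and self.xci_schedule is not None:
            raise SimConfigError(
                "xci_schedule given with dosage_mode='dampening'")
        for frac in (self.coexpression_level, self.maternal_carryover,
                     *self.wave_fractions):
            if not 0.0 <= frac <= 1.0:
                raise SimConfigError(f"fraction {frac} outside [0, 1]")
        sched = self.dampening_schedule or {}
        vals = [sched[d] for d in sorted(sched)]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise SimConfigError("dampening_schedule must be non-increasing")
        if not all(0.0 < v <= 1.0 for v in vals):
            raise SimConfigError("dampening factors must lie in (0, 1]")
        sched = self.xci_schedule or {}
        vals = [sched[d] for d in sorted(sched)]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise SimConfigError("xci_schedule must be non-decreasing")
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise SimConfigError("xci completion must lie in [0, 1]")

    def resolved_schedule(self) -> dict:
        if self.dosage_mode == "dampening":
            return dict(self.dampening_schedule or DEFAULT_DAMPENING_SCHEDULE)
        if self.dosage_mode == "xci":
            return dict(self.xci_schedule or DEFAULT_XCI_SCHEDULE)
        return {}


@dataclasses.dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated experiment (test oracle).

    ``cells`` carries the true pseudo-time, sex, lineage, TE subpopulation,
    per-cell X-allele activity factors and the degraded-cell flag; ``genes``
    carries program membership and activation wave.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    config: SimConfig


def x_allele_factors(mode: str, params: dict, day: int,
                     rng: np.random.Generator,
                     n_cells: int = 1) -> np.ndarray:
    """Per-cell pair of X-allele activity factors in [0, 1].

    two_active → (1, 1); dampening → (d, d) with d from the day schedule;
    xci → one whole allele silenced in a completion-fraction c of cells, the
    silenced allele chosen uniformly per cell.
    """
    if mode == "two_active":
        return np.ones((n_cells, 2))
    if mode == "dampening":
        if day not in params:
            raise SimConfigError(f"no dampening factor for day {day}")
        d = params[day]
        if not 0.0 < d <= 1.0:
            raise SimConfigError(f"dampening factor {d} outside (0, 1]")
        return np.full((n_cells, 2), float(d))
    if mode == "xci":
        if day not in params:
            raise SimConfigError(f"no xci completion for day {day}")
        c = params[day]
        if not 0.0 <= c <= 1.0:
            raise SimConfigError(f"xci completion {c} outside [0, 1]")
        factors = np.ones((n_cells, 2))
        silenced = rng.random(n_cells) < c
        which = rng.integers(0, 2, n_cells)
        factors[silenced, which[silenced]] = 0.0
        return factors
    raise SimConfigError(f"unknown dosage mode {mode!r}")


# ---------------------------------------------------------------------------
# gene and cell universes
# ---------------------------------------------------------------------------

def _build_gene_tables(config: SimConfig, rng: np.random.Generator):
    """Gene annotation, truth annotation and per-gene model parameters."""
    names, programs, waves, chroms = [], [], [], []

    def add(name, program, wave, chrom):
        names.append(name)
        programs.append(program)
        waves.append(wave)
        chroms.append(chrom)

    wave_names = ("early", "mid", "late")
    marker_pool = {"TE": TE_MARKERS, "EPI": EPI_MARKERS, "PE": PE_MARKERS}
    for lineage in LINEAGES:
        count = config.lineage_gene_counts[lineage]
        n_early = int(round(config.wave_fractions[0] * count))
        n_mid = int(round(config.wave_fractions[1] * count))
        bounds = [n_early, n_early + n_mid, count]
        markers = marker_pool[lineage]
        for i in range(count):
            wave = wave_names[int(np.searchsorted(bounds, i, side="right"))]
            name = markers[i] if i < len(markers) else f"{lineage}{i:03d}"
            add(name, lineage, wave, f"chr{rng.integers(1, 23)}")
    half = config.n_temporal_genes // 2
    for i in range(config.n_temporal_genes):
        kind = "temporal_up" if i < half else "temporal_down"
        add(f"T{i:03d}", kind, "", f"chr{rng.integers(1, 23)}")
    for i in range(config.n_polar_genes):
        name = POLAR_MARKERS[i] if i < len(POLAR_MARKERS) else f"POL{i:03d}"
        add(name, "polar", "", f"chr{rng.integers(1, 23)}")
    for i, name in enumerate(Y_MARKERS):
        add(name, "Y", "", "chrY")
    add("XIST", "XIST", "", "chrX")
    add("XACT", "XACT", "", "chrX")
    for i in range(config.n_x_genes):
        name = "ATRX" if i == 0 else f"X{i:03d}"
        add(name, "chrX", "", "chrX")
    n_hk = config.n_genes - len(names)
    if n_hk < 0:
        raise SimConfigError("n_genes smaller than the program genes")
    for i in range(n_hk):
        add(f"HK{i:04d}", "housekeeping", "", f"chr{rng.integers(1, 23)}")

    truth_genes = pd.DataFrame({"program": programs, "wave": waves},
                               index=pd.Index(names, name="gene_id"))
    start = rng.integers(1, 150_000_000, len(names))
    genes = pd.DataFrame({
        "chrom": chroms,
        "start": start,
        "length_bp": rng.integers(500, 10_000, len(names)),
        "is_spikein": False,
    }, index=truth_genes.index)

    # per-gene expression parameters
    params = pd.DataFrame(index=truth_genes.index)
    prog = truth_genes["program"]
    base = np.exp(rng.normal(np.log(8.0), 1.2, len(names)))
    # the TE program is the strongest axis (it drives the first split, as
    # in blastocysts where TE-ICM is the dominant lineage separation)
    base[prog == "TE"] = np.exp(
        rng.normal(np.log(20.0), 0.5, int((prog == "TE").sum())))
    for lin in ("EPI", "PE"):
        base[prog == lin] = np.exp(
            rng.normal(np.log(20.0), 0.5, int((prog == lin).sum())))
    # temporal genes carry the dominant stage signal, as in real embryos
    # where developmental time is the primary segregating factor
    temporal = prog.str.startswith("temporal")
    base[temporal] = np.exp(rng.normal(np.log(45.0), 0.5, int(temporal.sum())))
    base[prog == "polar"] = np.exp(
        rng.normal(np.log(22.0), 0.4, int((prog == "polar").sum())))
    base[prog == "Y"] = np.exp(
        rng.normal(np.log(35.0), 0.3, int((prog == "Y").sum())))
    # chrX expression matches the autosomal range so that X-vs-autosome
    # comparisons (ratio controls, allelic detection rates) are fair
    base[prog == "chrX"] = np.exp(
        rng.normal(np.log(12.0), 1.1, int((prog == "chrX").sum())))
    params["base"] = base
    params["midpoint"] = rng.uniform(3.0, 7.5, len(names))  # temporal genes
    is_program = ~prog.isin(["housekeeping", "chrX", "Y"])
    cv_bio = np.where(is_program, config.program_cv,
                      config.burst_dispersion)
    cv_bio[temporal] = config.temporal_cv
    params["cv_bio"] = cv_bio
    return genes, truth_genes, params


def _build_cells(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.cells_per_embryo
    x0_left = config.n_x0_embryos
    for day in sorted(config.n_embryos_per_day):
        n_embryos = config.n_embryos_per_day[day]
        for e in range(n_embryos):
            embryo = f"E{day}.{e + 1}"
            sex = "female" if e % 2 == 0 else "male"
            is_x0 = False
            if sex == "female" and day >= 5 and x0_left > 0:
                is_x0 = True
                x0_left -= 1
            t_embryo = day + rng.uniform(0.2, 0.8)
            n_cells = int(rng.integers(lo, hi + 1))
            for c in range(n_cells):
                t = float(np.clip(t_embryo + rng.uniform(-0.04, 0.04),
                                  day + 0.16, day + 0.84))
                rows.append((f"{embryo}_c{c + 1:02d}", embryo, day, "", sex,
                             t, is_x0))
    cells = pd.DataFrame(rows, columns=["cell_id", "embryo_id", "day",
                                        "subday", "sex", "t_true", "is_x0"])
    cells = cells.set_index("cell_id")

    committed = cells["t_true"] >= config.commit_day
    lineage = np.where(committed,
                       rng.choice(LINEAGES, len(cells),
                                  p=[0.44, 0.28, 0.28]),
                       "pre")
    cells["lineage"] = lineage
    te_subpop = np.full(len(cells), "NA", dtype=object)
    for embryo, members in cells.groupby("embryo_id").groups.items():
        sub = cells.loc[members]
        te = sub.index[(sub["lineage"] == "TE") & (sub["day"] >= 6)]
        if len(te) == 0:
            continue
        n_polar = len(te) // 2 + (len(te) % 2)  # half of each embryo's TE
        chosen = rng.permutation(len(te))[:n_polar]
        te_subpop[cells.index.get_indexer(te[chosen])] = "polar"
        rest = np.setdiff1d(np.arange(len(te)), chosen)
        te_subpop[cells.index.get_indexer(te[rest])] = "mural"
    cells["te_subpop"] = te_subpop
    return cells


# schedules of cell-state programs, per day
_XIST_FEMALE = {3: 2.0, 4: 10.0, 5: 30.0, 6: 60.0, 7: 80.0}
_XACT_FEMALE = {3: 0.0, 4: 20.0, 5: 15.0, 6: 10.0, 7: 8.0}
_Y_ZGA_FACTOR = {3: 0.45, 4: 1.0, 5: 1.0, 6: 1.0, 7: 1.0}


def _expected_means(config: SimConfig, cells: pd.DataFrame,
                    truth_genes: pd.DataFrame, params: pd.DataFrame,
                    x_total: np.ndarray) -> np.ndarray:
    """Deterministic expected RPKM matrix (genes × cells)."""
    n_g, n_c = len(truth_genes), len(cells)
    mu = np.zeros((n_g, n_c))
    prog = truth_genes["program"].to_numpy()
    wave = truth_genes["wave"].to_numpy()
    base = params["base"].to_numpy()
    mid = params["midpoint"].to_numpy()

    t = cells["t_true"].to_numpy()
    day = cells["day"].to_numpy()
    sex = cells["sex"].to_numpy()
    lineage = cells["lineage"].to_numpy()
    te_subpop = cells["te_subpop"].to_numpy()
    committed = t >= config.commit_day

    mu_off = 0.5
    hk = prog == "housekeeping"
    mu[hk] = base[hk, None]

    for lin in LINEAGES:
        sel = prog == lin
        # TE genes stay expressed in all post-commitment cells, only
        # higher in TE proper; EPI/PE genes are lineage-specific
        leak = config.te_leak_level if lin == "TE" else 0.0
        for w, onset in WAVE_ONSET.items():
            g = sel & (wave == w)
            if not g.any():
                continue
            active = t >= onset
            own = (lineage == lin) & committed & active
            coexpr = ~committed & active
            leaky = committed & (lineage != lin) & active
            mu[np.ix_(g, own)] = base[g, None]
            mu[np.ix_(g, coexpr)] = (config.coexpression_level
                                     * base[g, None])
            off = ~(own | coexpr)
            mu[np.ix_(g, off)] = mu_off
            if leak > 0 and leaky.any():
                mu[np.ix_(g, leaky)] = np.maximum(leak * base[g, None],
                                                  mu_off)
            if lin in ("EPI", "PE"):
                sibling = "PE" if lin == "EPI" else "EPI"
                cross = committed & (lineage == sibling) & active
                if cross.any():
                    lvl = np.array([config.icm_cross_schedule.get(d, 0.0)
                                    for d in day[cross]])
                    mu[np.ix_(g, cross)] = np.maximum(
                        lvl[None, :] * base[g, None], mu_off)

    up = prog == "temporal_up"
    down = prog == "temporal_down"
    sig_up = 1.0 / (1.0 + np.exp(-(t[None, :] - mid[up, None]) / 0.6))
    mu[up] = mu_off + base[up, None] * sig_up
    sig_dn = 1.0 / (1.0 + np.exp(-(t[None, :] - mid[down, None]) / 0.6))
    mu[down] = mu_off + base[down, None] * (1.0 - sig_dn)

    pol = prog == "polar"
    polar_cells = te_subpop == "polar"
    mu[pol] = 0.2
    mu[np.ix_(pol, polar_cells)] = base[pol, None]

    ymask = prog == "Y"
    male = sex == "male"
    zga = np.array([_Y_ZGA_FACTOR[d] for d in day])
    mu[np.ix_(ymask, male)] = (base[ymask, None] * zga[None, male])

    female = sex == "female"
    xist = truth_genes.index.get_loc("XIST")
    mu[xist, female] = np.array([_XIST_FEMALE[d] for d in day[female]])
    mu[xist, male] = np.array([_XIST_FEMALE[d] for d in day[male]]) / 15.0
    xact = truth_genes.index.get_loc("XACT")
    mu[xact, female] = np.array([_XACT_FEMALE[d] for d in day[female]])
    mu[xact, male] = np.array([_XACT_FEMALE[d] for d in day[male]]) / 2.0

    # chrX dosage: base is the one-active-X level; female output scales with
    # the sum of the two allele activity factors.
    xg = prog == "chrX"
    mu[xg] = base[xg, None] * x_total[None, :]
    return mu


def _sample_expression(mu: np.ndarray, r: np.ndarray, a1: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson with amplification a1: CV² = a1/μ + 1/r."""
    shape = np.broadcast_to(r[:, None], mu.shape)
    lam = rng.gamma(shape, mu / (a1 * shape))
    return a1 * rng.poisson(lam).astype(float)


def _apply_dropout(values: np.ndarray, mu: np.ndarray, shape: tuple,
                   rng: np.random.Generator) -> np.ndarray:
    x0, scale = shape
    p_keep = 1.0 / (1.0 + np.exp(-(np.log2(mu + 1.0) - x0) / scale))
    keep = rng.random(values.shape) < p_keep
    return values * keep


def simulate_experiment(config: SimConfig):
    """Generate (ExpressionDataset, allele-count table, SimTruth).

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, truth_genes, params = _build_gene_tables(config, rng)
    cells = _build_cells(config, rng)

    # per-cell X allele factors
    schedule = config.resolved_schedule()
    factors = np.ones((len(cells), 2))
    female = cells["sex"].to_numpy() == "female"
    for day in sorted(set(cells["day"])):
        sel = np.flatnonzero(female & (cells["day"].to_numpy() == day))
        if len(sel):
            factors[sel] = x_allele_factors(config.dosage_mode, schedule,
                                            day, rng, len(sel))
    male = ~female
    factors[male, 1] = 0.0      # single X
    x0 = cells["is_x0"].to_numpy(bool)
    factors[x0, 1] = 0.0        # X0 female embryos: one X only
    cells["x_factor1"] = factors[:, 0]
    cells["x_factor2"] = factors[:, 1]
    x_total = factors.sum(axis=1)

    mu = _expected_means(config, cells, truth_genes, params, x_total)
    a1, alpha0 = config.tech_noise
    r_bio = 1.0 / (alpha0 + params["cv_bio"].to_numpy() ** 2)
    values = _sample_expression(mu, r_bio, a1, rng)
    values = _apply_dropout(values, mu, config.dropout_shape, rng)

    # spike-ins: purely technical noise, no dropout
    spike_mu = np.geomspace(0.5, 500.0, config.n_spikeins)
    spike_means = np.broadcast_to(spike_mu[:, None],
                                  (config.n_spikeins, len(cells))).copy()
    r_spike = np.full(config.n_spikeins, 1.0 / alpha0)
    spike_values = _sample_expression(spike_means, r_spike, a1, rng)
    spike_ids = [f"ERCC-{i:04d}" for i in range(config.n_spikeins)]
    spike_genes = pd.DataFrame({
        "chrom": "spikein", "start": 1,
        "length_bp": rng.integers(500, 2000, config.n_spikeins),
        "is_spikein": True,
    }, index=pd.Index(spike_ids, name="gene_id"))

    all_values = pd.DataFrame(
        np.vstack([values, spike_values]),
        index=truth_genes.index.append(spike_genes.index),
        columns=cells.index)
    all_genes = pd.concat([genes, spike_genes])
    meta = cells[["embryo_id", "day", "subday", "sex"]].copy()
    meta["qc_pass"] = True
    dataset = ExpressionDataset(all_values, all_genes, meta)

    allele_table = _sample_allele_counts(config, cells, genes, truth_genes,
                                         values, factors, rng)

    truth_cells = cells.copy()
    truth_cells["degraded"] = False
    truth = SimTruth(truth_cells, truth_genes, config)
    return dataset, allele_table, truth


def _sample_allele_counts(config, cells, genes, truth_genes, values,
                          factors, rng) -> pd.DataFrame:
    """Beta-binomial allele read counts for heterozygous SNVs.

    Every embryo is heterozygous at every SNV; reference/alternative labels
    are arbitrary, randomised per (embryo, SNV).  Male chrX reads are
    monoallelic except for maternal carryover at E3.
    """
    n_cells = len(cells)
    day = cells["day"].to_numpy()
    male = cells["sex"].to_numpy() == "male"
    is_x = (genes["chrom"] == "chrX").to_numpy()
    embryos = cells["embryo_id"].to_numpy()
    embryo_ids = pd.unique(embryos)
    embryo_idx = pd.Series(np.arange(len(embryo_ids)),
                           index=embryo_ids)[embryos].to_numpy()

    frames = []
    with np.errstate(invalid="ignore"):
        denom = factors.sum(axis=1)
        p_female = np.where(denom > 0, factors[:, 1] / np.maximum(denom, 1e-12),
                            0.5)
    for k in range(config.het_snv_per_gene):
        total = rng.poisson(config.snv_coverage * values)
        # minor-allele probability per (gene, cell)
        p = np.empty((len(genes), n_cells))
        p[:] = 0.5                      # autosomes: both alleles active
        p[is_x] = p_female[None, :]     # females follow allele factors
        male_x = np.zeros((len(genes), n_cells), bool)
        male_x[np.ix_(is_x, male)] = True
        p[male_x] = 0.0
        carry = male_x & (day[None, :] == 3)
        p[carry] = config.maternal_carryover
        # random ref/alt orientation per (embryo, SNV)
        orient = rng.random((len(genes), len(embryo_ids))) < 0.5
        flip = orient[:, embryo_idx]
        p = np.where(flip, 1.0 - p, p)

        nu = config.allele_concentration
        interior = (p > 0) & (p < 1)
        q = p.copy()
        q[interior] = rng.beta(p[interior] * nu, (1 - p[interior]) * nu)
        alt = rng.binomial(total, q)
        ref = total - alt

        gi, ci = np.nonzero(total > 0)
        frames.append(pd.DataFrame({
            "cell_id": cells.index.to_numpy()[ci],
            "snv_id": np.char.add(genes.index.to_numpy().astype(str)[gi],
                                  f"_snv{k}"),
            "chrom": genes["chrom"].to_numpy()[gi],
            "pos": genes["start"].to_numpy()[gi] + 100 * k,
            "gene_id": genes.index.to_numpy()[gi],
            "ref_reads": ref[gi, ci],
            "alt_reads": alt[gi, ci],
        }))
    table = pd.concat(frames, ignore_index=True)
    return table[ALLELE_COLUMNS].sort_values(
        ["cell_id", "chrom", "pos"], kind="stable").reset_index(drop=True)


def degrade_cells(dataset: ExpressionDataset, n_bad: int, seed: int,
                  truth: SimTruth | None = None) -> ExpressionDataset:
    """Replace ``n_bad`` random cells with within-cell gene-permuted profiles.

    Permuting a cell's values across genes destroys the shared
    mean-expression structure, so degraded cells lose their correlation to
    every intact cell — the fixture for quality-control tests.  Flags the
    chosen cells in ``truth`` when given.
    """
    if n_bad >= dataset.n_cells:
        raise ValueError("n_bad must be smaller than the number of cells")
    out = dataset.copy()
    if n_bad == 0:
        return out
    rng = np.random.default_rng(seed)
    bio = ~out.genes["is_spikein"].to_numpy(bool)
    chosen = rng.choice(dataset.n_cells, size=n_bad, replace=False)
    arr = out.values.to_numpy()
    for c in chosen:
        col = arr[bio, c]
        arr[bio, c] = col[rng.permutation(len(col))]
    out.values.iloc[:, :] = arr
    if truth is not None:
        truth.cells.loc[out.cells.index[chosen], "degraded"] = True
    return out
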