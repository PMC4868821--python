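# Methods

`embryolin` re-implements, as a tested pipeline over synthetic data with
known truth, the staged analysis of single-cell RNA-seq from human
preimplantation embryos (embryonic days E3–E7): quality control and sex
classification, spike-in-calibrated variable-gene selection,
principal-curve pseudo-time, hierarchical lineage classification
(pre-lineage → ICM/TE → EPI/PE, polar/mural TE), lineage-specific gene
statistics, lineage-segregation dynamics, X-chromosome dosage-compensation
statistics and allele-level analysis that distinguishes biallelic
*dampening* of both X chromosomes from conventional X inactivation (XCI).

## The synthetic-data generator

Because the sequenced embryo dataset is not redistributable, every stage
is exercised on data from `embryolin.simulate`, which emulates the
*structure* of a Smart-seq2 RPKM experiment rather than reads.

**Cells.** Embryos are sampled on days 3–7 (default 4/4/8/8/8 embryos per
day, 10–14 cells each, ≈370 cells — a deliberately desk-scale version of
a study with 81–466 cells per day). An embryo collected on day *d* has a
true developmental time drawn uniformly in (d+0.2, d+0.8); its cells
share that time up to ±0.04 days. Embryo sex alternates within a day.
Cells with time ≥ `commit_day` (default 5.0) commit to TE (44%), EPI or
PE (28% each); at E6–E7, half of each embryo's TE cells are polar, half
mural.

**Genes** (1600 biological + 60 spike-ins by default):

* *Temporal program* (250 genes, the dominant variance component, as
  developmental stage is in real embryos): logistic activation or decay
  with midpoints spread over the whole time range, on-level ≈45 RPKM.
* *Lineage programs* (100 genes each for TE/EPI/PE) switch on in
  activation waves (early/mid/late; onsets at t = 4, 5, 6). Uncommitted
  cells co-express the active waves of all three programs at
  `coexpression_level` (0.5) of the committed level — the intermediate
  co-expression state. Committed cells express their own program fully;
  TE genes additionally stay expressed in *all* committed cells at a leak
  level of 0.25 (in the embryos TE genes are expressed everywhere from E5
  on, only higher in TE), and the EPI and PE programs remain partially
  cross-expressed within the ICM (factor 0.2), so the ICM–TE axis is the
  dominant per-day split and the EPI–PE contrast the weaker, nested one.
  TE on-levels (~20 RPKM) exceed EPI/PE (~11–20) for the same reason.
* *Polar program* (40 genes) up only in polar TE cells at E6–E7.
* *Sex-linked structure*: 12 chrY genes expressed only in male cells,
  reduced to 45% of their later level at E3 (zygotic genome activation
  incomplete but not absent — male E3 cells must remain sex-classifiable,
  as they were in practice); XIST rising in females from E4 with ~15-fold
  lower sporadic male expression; XACT activated at E4 in both sexes;
  120 chrX genes whose base expression is drawn from the *autosomal*
  range (lognormal, median ≈12 RPKM) so that X-vs-autosome comparisons —
  ratio controls and allelic detection rates — are fair.

**X dosage.** Each chrX gene's base level is the one-active-X output; a
female cell's expected expression is base × (f₁+f₂) where (f₁, f₂) are
its per-allele activity factors: `two_active` → (1,1); `dampening` →
(d,d) with d from a non-increasing day schedule (default reaching 0.55 at
E7, i.e. a female:male ratio of 1.1 — most of the way to compensation);
`xci` → whole-cell silencing of one uniformly chosen allele in a
completion fraction c of cells (non-decreasing schedule, default 0.6 at
E7). Whole-cell (not gene-by-gene) silencing is deliberate: it matches
the resolution at which the biallelic-fraction statistics operate.

**Noise.** Expression is Gamma–Poisson (negative binomial) on the
expected RPKM with an amplification factor, giving CV² = a1/μ + 1/r;
spike-ins use r = 1/α₀ (pure technical noise, defaults a1 = 4, α₀ =
0.05), biological genes add a per-gene biological CV (0.3 housekeeping,
0.4 temporal, 0.5 lineage/polar programs). A mean-dependent logistic
dropout (midpoint 0.7 on log2(μ+1), scale 0.5) zeroes low-expression
observations; spike-ins are exempt.

**Allele counts.** Every embryo is heterozygous at one SNV per gene
(configurable). SNV read totals are Poisson with expectation 0.3 reads
per RPKM unit of the cell's sampled expression; the alternative-allele
count is beta-binomial (concentration 40) around the cell's allele ratio
— 0.5 on autosomes, f₂/(f₁+f₂) on female chrX, 0 or 1 on male chrX
(labels randomised per embryo and SNV; all downstream statistics are
phase-free). Male E3 chrX reads carry a maternal-transcript fraction of
0.3 (decayed to 0 from E4), reproducing the lingering-maternal-RNA
signal.

**What the generator does not emulate.** Read-level artefacts (mapping
bias, PCR duplicates), gene-length effects, doublets, cell-cycle
structure, embryo aneuploidies other than the optional X0 embryos,
gene-by-gene spreading of XCI, and the long-tailed SNV coverage of real
dbSNP sites. Passing tests therefore demonstrate that the statistical
machinery is correct and well calibrated on data with this structure, not
that it is robust to every artefact of real libraries.

## Stage-by-stage notes

**QC and sex.** A cell passes QC iff its maximum Spearman correlation to
any other cell is ≥0.63, computed on log2(RPKM+1) over all non-spike-in
genes (the log transform is configurable; rank statistics make it almost
immaterial). Sex: Y-RPKM sum <50 → female, >100 → male, else unknown;
embryo sex is the majority vote, with a conflict flag. The Y-gene ZGA
summary normalises each male cell's mean Y expression to the E4–E7
median.

**Variable genes.** Technical noise CV² = a1/μ + α₀ is fitted on
spike-ins by two-pass weighted least squares (weights 1/CV²-predicted²;
unweighted OLS lets the noisy low-mean spike-ins bias α₀ by ~40%). A
gene's score is observed CV² divided by (a1/μ + α₀ + cv_bio²) with
cv_bio = 0.5; a chi-square tail probability accompanies the ratio
(Brennecke-style). Ties in the ranking break by gene ID.

**Embedding and pseudo-time.** Cells are embedded on the top-500 genes by
t-SNE, PCA, or a deterministic diffusion map (Gaussian kernel,
median-distance bandwidth, symmetric normalisation, dense
eigendecomposition, sign-fixed components). The pipeline default is the
diffusion map: at a few hundred cells t-SNE's cluster-preserving layout
repeatedly broke the arc-length parametrisation the principal curve
needs, while the diffusion map and PCA order cells stably.

The principal curve is Hastie–Stuetzle: lowess-smooth each coordinate
against the current arc length (span 0.3), re-project all cells onto the
polyline, iterate. Iterations stop as soon as the mean squared projection
distance improves by less than 5% — without this the curve keeps folding
into the late-stage lineage fan, which lowers projection distance while
destroying the time ordering (a classic principal-curve overfit).

Pseudo-time units: arc length is oriented by day labels and calibrated so
one embryonic day spans 2.5 units, with 12.5 at the E5 boundary. The
calibration interpolates monotonically between per-day median embryo arc
lengths, anchoring the day-d cohort median at 2.5 × (d + 0.5) (embryos
sampled during day d average half a day in). A single affine map (also
available, `rescale="linear"`) under-corrects because arc length is not
uniform in developmental time — late stages traverse longer
transcriptional distances — and then misplaces whole day cohorts
relative to the pre-lineage gate. The whole scale is a reconstruction;
the gate value 12.5 carries the operational meaning "embryos younger than
mid-E5" and is a config parameter.

**Lineage calls.** Per day ≥5, embryos below pseudo-time 12.5 are
pre-lineage; remaining cells are split by PAM (k-medoids with greedy
BUILD initialisation and best-improvement SWAP — deterministic, no seed)
on the first two principal components of the day's top-250 variable
genes; clusters are named by marker panels (weighted mean of z-scored log
expression, weights −1/+1; defaults use the field's named markers and
ship as editable config). ICM cells are then split EPI/PE the same way;
E6/E7 TE cells are split polar/mural on a 50-gene panel (the polar signal
lives in ~40 genes; diluting it into 250 genes buries the split) and
named by the polar-gene z-score.

*No-split gate.* A split is accepted only if its mean silhouette reaches
0.2, with silhouette computed on log-expression distances over the
clustering gene set, **not** in the 2-PC subspace: with a few dozen cells
and 250 genes, PCA overfits noise so badly that unstructured data scores
*higher* silhouette in PC space (0.6–0.75) than genuinely split data —
while in gene space nulls concentrate at 0.10–0.18 and true splits sit at
0.2–0.45. The gate value is calibrated on simulated unstructured days
(null maximum ≈0.18 over repeated seeds) and is config-exposed.

**Differential expression.** Two-sided Wilcoxon rank-sum per gene on
log2(RPKM+1) (a robust, dependency-free stand-in for a parametric
single-cell error model; the test is pluggable), signed z from the
pseudo-counted fold change, genes expressed in <10% of both groups
excluded, Benjamini–Hochberg FDR. Lineage specificity combines one
lineage's two pairwise contrasts by Stouffer's Σz/√k, and maintained
genes combine the per-day results across E5–E7; "significant" means
FDR ≤5% *and* positive z (specific to that lineage, not merely
different). Because the two combined contrasts share the lineage's own
cells, the combined null z is over-dispersed by roughly √1.5, so the
nominal FDR is mildly anticonservative; the maintained-TE list still
reaches ≥90% precision against simulation truth, EPI/PE slightly less
(~0.8–0.9). Genes absent from any day's ranking (e.g. late-wave genes
not yet expressed at E5) are excluded from the maintained combination.

**Embryo variability.** The within-embryo variability score (CV² of
log expression across an embryo's cells) is defined only where the gene
is expressed (mean RPKM ≥1 in that embryo): CV² of an off gene is
dominated by its near-zero mean and would always "peak" at E3.

**Segregation.** Diffusion map on the maintained lineage genes (3
components), linear SVM (C = 1) fitted on matured cells only.
Coordinates are standardised on the training cells before the fit — the
embedding's raw scale is arbitrary (~1e-4) and a fixed soft-margin C
needs unit-order features; distances are therefore in normalised
component units. The segregation-vs-time curve is per-embryo mean
|distance|; the changepoint is the best two-level piecewise-constant
least-squares split, reported as the time of the first embryo on the high
level, and flagged undefined when no split improves on a constant fit by
more than 1%.

**X dosage.** Per-gene female:male ratios use pseudo-counted means
((mean_f+1)/(mean_m+1)) over genes transcribed (mean ≥1 RPKM) in at
least one sex; chromosome-wide tracks average the 25 positionally
nearest expressed genes (rank window sliding inside the chromosome ends);
total X output uses a gene set fixed across days. The X0 screen compares
an embryo's windowed chrX profile (log scale) with same-day female and
male references and flags a sex-called-female embryo closer to the male
reference over ≥80% of positions.

**Allelic analysis.** A (cell, SNV) observation is undetected below 3
reads, biallelic when the minor allele has ≥2 reads and ≥10% of reads,
else monoallelic. These thresholds are reconstructions (the original
cutoffs are not published at this granularity); they are config-exposed
and the dampening-vs-XCI discrimination is verified across minor-fraction
settings of 0.05/0.1/0.2. Per-cell biallelic fractions require ≥25
detected chrX SNVs; the discriminating statistic is the chrX:autosome
ratio of biallelic fractions — ≈1 under dampening (both alleles stay
active), falling toward 0 as XCI completes.

## Problem sizes

Default runs use ≈370 cells × 1660 genes; the dosage and allelic
analyses use single-day cohorts of 12–22 embryos (≈150–460 cells); the
false-split calibration uses 20 independent two-day simulations. These
sizes keep a full test-and-analysis cycle in a few minutes on one CPU
while leaving every statistic comfortably powered; all are config fields
and scale up transparently.

## Known limitations

* The pseudo-time scale is supervised by day labels (orientation and the
  monotone calibration); it refines ordering *within* days but cannot
  contradict a grossly wrong day labelling.
* The silhouette gate value (0.2) is calibrated on this generator's
  noise structure; real data with different dropout or depth may need
  recalibration (it is a config field).
* Stouffer combination over contrasts sharing a group is mildly
  anticonservative (see above); treat maintained-gene FDRs as ranks more
  than exact error rates.
* The allelic thresholds are reconstructions; absolute biallelic
  fractions shift with coverage, which is why all conclusions rest on
  the chrX:autosome *ratio* rather than raw fractions.
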