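# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `hscage`, in the spirit of a package
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Single-cell processing

Quality control removes cells with fewer than 800 detected genes
(strictly: a cell with exactly 800 is kept) or more than 5% mitochondrial
transcripts; mitochondrial genes are recognized by a configurable id
prefix (default `mt-`, organism-dependent). QC is idempotent and reports
removal counts per criterion.

Normalization is `ln(1 + count / cell_total × scale)` with scale 10⁴
(natural log, +1 pseudocount). This keeps zeros exactly zero and makes
per-cell profiles library-size invariant, so downstream fold-change
thresholds on the natural-log scale are comparable to the conventions of
the mainstream single-cell toolchains.

Variable genes are ranked by a binned-dispersion statistic: the variance
of each gene's log-normalized expression is z-scored against genes in the
same equal-occupancy mean bin (20 bins), so selection is not a proxy for
expression level. Constant genes can never outrank genes with positive
variance; ties break lexicographically.

Clustering is deliberately minimal: PCA on z-scored variable genes
(default 20 components) followed by seeded k-means. The cascade only needs
quiescent-subcluster labels ranked by aging score, not a faithful
reproduction of any particular graph-based partition whose resolution
parameters are unknown; external labels can be supplied to bypass
clustering entirely. On the generator's default separation this recovers
the planted clusters essentially perfectly (adjusted Rand index ≈ 1, and
≥ 0.8 is asserted across seeds in the tests).

## Signature scores and cell cycle

A signature score is the per-cell mean of across-cell z-scores of the set
genes. The z-mean form is deterministic and bin-free; it differs
numerically from control-bin "module scores" but ranks cells equivalently
for the separations tested here, and the scoring method is tagged on the
result so a control-bin variant can be added without breaking interfaces.
Constant genes contribute 0 rather than NaN — a stability choice for
sparse data.

Cell-cycle phases use S and G2/M signature scores; a cell is assigned the
argmax phase when that score is positive ("expressed" is operationalized
as above the dataset mean, since no threshold is published), otherwise
G0/G1, with exact positive ties resolved conservatively to G0/G1. Default
S/G2M gene lists ship as plain-text fixtures (mouse-cased versions of the
standard single-cell toolkit lists).

## Differential testing

*Single cell.* Two-sided Wilcoxon rank-sum on log-normalized expression.
Genes are prefiltered by detection fraction (min.pct 0.25 in at least one
group; "both groups" is available) and by natural-log fold change
|lnFC| ≥ 0.25, where lnFC = ln((mean(expm1 x_A)+1)/(mean(expm1 x_B)+1)).
The p-value uses the normal approximation with tie and continuity
corrections; when both groups have ≤ 10 cells it switches to exact
enumeration of all label assignments on midranks, which the tests verify
against an independent pairwise-comparison permutation oracle for every
group-size combination up to 8. BH adjustment runs over tested genes only.

*Bulk RNA.* Welch t on log2(CPM+1), BH adjustment, significance iff
adjusted p < 0.05 and fold change > 2 or < 0.5 (fold change computed on
mean CPM with a +1 stabilizer). The t-on-log-CPM estimator replaces a
negative-binomial Wald test deliberately: the calling rule, not the
estimator, is what this pipeline standardizes, and each record is tagged
with the test that produced it so an NB GLM can be slotted in.

*Chromatin accessibility.* Same estimator on peak counts, but significance
uses the **raw** p < 0.05 with fold change > 1.5 or < 0.67. The raw-p rule
for peaks alongside the adjusted-p rule for RNA is an intentional
asymmetry inherited from the upstream protocol; records carry a
`p_criterion` tag so users see which rule produced each call.

*Null calibration.* The type-I-error simulations run with both prefilters
disabled (min.pct 0, lnFC 0): the effect-size prefilters select on the
observed fold change and would bias null p-values downward, so calibration
measures the test itself. Acceptance checks assert the empirical raw-p
rejection rate at nominal 0.05 lies in [0.03, 0.07] for both tests
(Wilcoxon: 200 null datasets × 300 genes, 50 vs 50 cells; bulk: 20
datasets × 500 genes, 5 vs 5 replicates), and that the BH-adjusted
rejection rate stays ≤ 0.07.

*Peaks.* Consensus peaks merge the interval union of all replicate peaks
(the reference universe is configurable to "first replicate") and keep
intervals overlapping ≥ 1 bp of a peak in strictly more than 60% of
replicates — 3 of 5 is dropped. Peak-to-gene assignment uses the gap
between half-open intervals with an inclusive 5,000-bp window (a gene at
exactly 5 kb is assigned). Region-set signal averages per-sample
reads-per-million over the universe peaks overlapping each region.

## Marker cascade

Stage 1 keeps the top K = 150 genes by Pearson correlation with the aging
score (signed ranking by default; the alternative absolute-value ranking
is a flag, since either reading of "strong correlation" is defensible).
Stage 2 intersects with the aging-upregulated set; stage 3 requires the
membrane annotation; stage 4 requires the candidate's mean expression in
the target (young-like) cluster to be below its mean in *each* aged
cluster **and** a one-sided rank-sum p < 0.05 against the pooled aged
clusters — the test guards against noise-driven passes of the qualitative
criterion. Ties at the K boundary and in the final ranking break
lexicographically for determinism. The final choice among candidates
(antibody availability, specificity) is human judgment: the cascade ranks,
it does not decide.

Feature-gene sets use |r| ≥ 0.7 between bulk log2(CPM+1) and marker
protein level across quartile samples; the threshold is exposed because
only the resulting set sizes, not the cutoff, are ever published for such
analyses. Marker level is always an external per-sample value (FACS
protein), never inferred from the expression matrix.

## Epigenetic clock

The clock is linear: age = intercept + Σ w_i β_i over its CpG sites, in
months. β values with coverage below 3× are masked first (coverage exactly
3 is kept). Sites missing after filtering are imputed with the clock's
training-mean β, and samples with under 80% of clock sites observed are
flagged but still reported — both robustness choices for RRBS dropout, and
both configurable. Training a clock is out of scope; weights load from a
TSV (site, weight, training mean, one intercept row).

With training-mean imputation, a missing site contributes the cohort-mean
age signal instead of the sample's own, so dropout biases extreme-age
predictions toward the middle; the acceptance criterion bounds the pooled
RMSE under 20% dropout at ≤ 1.5× the full-coverage noise floor. RMSEs are
pooled across simulation replicates before taking the ratio (a per-replicate
ratio of 12-sample RMSEs would be upward-biased by the noisy denominator).

## Cohort analytics

Functionality retention operationalizes "percent functionality relative to
a reference" as donor-vs-competitor odds per transplanted cell:
100 · [(C_t/(1−C_t))/dose_t] / [(C_r/(1−C_r))/dose_r], averaged over
timepoints. Odds-per-cell is dose-equivariant (doubling the test dose
halves retention) and equals 100% for statistically identical populations;
the plain chimerism ratio is available as a method flag since the
published figure's formula is not stated. Chimerism at exactly 0 or 1 is
an error (odds undefined).

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
`lifelines` behind this module's interface, with deaths processed before
censorings at tied times; the tests pin them to hand-worked product-limit
and log-rank examples. Median lifespan is the smallest t with S(t) ≤ 0.5;
"maximum lifespan" defaults to the longest observed death time, with a
top-decile-mean variant because gerontology usage varies. T-cell subsets
are threshold gates on CD44/CD62L intensity (naive = CD62L⁺CD44⁻, Tcm =
CD62L⁺CD44⁺, Tem = CD62L⁻CD44⁺, plus "other"), with thresholds supplied,
not fitted.

## Synthetic data: what it emulates, what it does not

All generators are deterministic under a fixed seed, with fixed substream
tags so one generator's draw count never perturbs another's.

*Single cell.* Counts are negative binomial (gamma–Poisson, gene-level
dispersion 0.3) around log-normal baseline means, scaled by per-cell
library factors (0.7–1.3). The central device is a latent per-cell aging
axis a ∈ [0, 1]: young cells (cluster q4) at 0, old clusters q1 (0.90–1.0)
and q2 (0.75–0.95) high, q3 (0.05–0.25) young-like. Aging genes (default
50, log2FC 1.5) and the membrane marker (default log2FC 2.0) multiply
their means by 2^(effect · a), so the marker–aging-score correlation the
cascade must find is an emergent property of the axis, not a hard-coded
answer. Because aged clusters average a ≈ 0.9 rather than 1, the realized
aged-vs-young fold change is ≈ 0.9× the nominal effect; the recovery test
measures it on raw pseudobulk counts (library factors are
condition-independent), which avoids the compositional shrinkage that CPM
normalization introduces when many genes move in one direction. Each
cluster additionally gets its own 40-gene module (log2FC 1.5) so
clustering is identifiable, and a 30-gene "young" module loads negatively
on the axis. Membrane annotation marks the marker plus 30 decoy genes
drawn from outside the aging set. Default sizes are 1,000 genes (10
mitochondrial) × 400 young + 600 old cells — large enough for the 800-gene
QC default to be meaningful, small enough that the 20-seed recovery runs
finish in seconds each.

*Bulk quartiles.* The same gene model produces G1–G4 samples (3 replicates
each, NB dispersion 0.02 as appropriate for sorted-population libraries)
whose group axis levels ascend through the quartile midpoints
(0.125…0.875); marker protein level is the group axis plus Gaussian noise
(sd 0.04), deliberately distinct from the marker's mRNA count, mirroring
FACS-vs-transcript measurement.

*Methylation.* β_i = clip(μ_i + s_i·age + ε, 0, 1) with μ_i ∈ [0.30, 0.60],
|s_i| ∈ [0.004, 0.010] per month (signs mixed), ε ~ N(0, 0.08) — β noise of
0.08 is realistic for RRBS at ~12× coverage — across 12 samples evenly
spaced over 3–24 months of mouse age, plus 20 signal-free sites. The clock
is exact by construction (w_i = s_i/Σs², intercept −Σw_iμ_i), so zero-noise
prediction recovers age to float precision, which the tests use as an
identity check.

*Cohorts.* Four groups (young, CD150low, whole, CD150high; 17 mice each,
2,000 cells transplanted) with logit-normal chimerism (sd 0.3) around group
trajectories over days 28–112 chosen so that the low/high subsets retain
roughly 73% and 6% of the young reference's per-cell repopulation odds;
multinomial lineage counts; bivariate log-normal CD44/CD62L mixtures with
group-dependent naive/Tcm/Tem mixing; and Gompertz survival (b = 0.35 per
month after transplantation) with group hazard ratios 0.65 / 1.0 / 1.09 and
administrative censoring at 36 months.

Not emulated: doublets, ambient RNA, batch effects, sequencing error,
informative censoring, per-mouse chimerism autocorrelation across
timepoints. Passing parameter-recovery tests therefore demonstrates the
pipeline's correctness and calibration under a faithful statistical
caricature of the study design — not robustness to the full messiness of
real data.

## Problem sizes and numerical details

The default test suite and the acceptance script keep simulations at the
sizes above (the package's chosen study-scale defaults): 20-seed recovery
runs for the cascade and clock, 200 null datasets for single-cell
calibration, 2,000 replicates for the log-rank null at n = 17 per group.
Degenerate inputs are handled explicitly and tested: all-equal marker
levels (stable-order binning with a warning), constant genes (zero
correlation, flagged), zero-variance scores and empty clusters (errors),
all-censored survival (flat curve, undefined median flagged). All
correlations are direct float64 summation; no iterative fits are involved
anywhere, so there are no convergence parameters.

## Known limitations

* The clustering is k-means-based and unsuitable for datasets whose
  subpopulations are not roughly convex in PC space; supply external
  labels in that case.
* The bulk/peak tests assume approximate normality of log CPM across
  replicates; at very low counts or n = 2 they lose power long before they
  lose calibration.
* The cascade's stage-2 filter is only as good as the supplied
  aging-upregulated set; with the pipeline's self-derived set (Wilcoxon
  DE, adjusted p < 0.05, up in old) the planted marker is recovered, but
  on real data curated sets are preferable.
* Retention assumes a shared competitor compartment and proportional
  engraftment odds; it is a summary statistic, not an engraftment model.
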