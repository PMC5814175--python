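# Methods

cyclederg packages the statistical machinery of a cell-cycle pharmacology
study of head-and-neck squamous cell carcinoma (HNSCC): a pan-cancer
gene-set deregulation statistic, quartile-stratified survival analysis,
treated-vs-control differential expression with over-representation
analysis, and the bench quantification arithmetic (dose-response IC-x,
2^-ddCt, densitometry, phase fractions, tumor volume). Everything is
exercisable end-to-end on synthetic data with known ground truth.

## Gene-set deregulation statistic

For one cohort, the statistic is

    log2FC = median_{g in S}( m_g ) - median_{g not in S}( m_g ),

where `m_g` is gene g's median log2 expression across the cohort's samples
and S is the gene set (in the motivating application, the GO "cell cycle"
members). Because the data are log2, a difference of medians is a log2
fold change. Aggregation order is per-gene medians first, then the
set-vs-rest median over genes; this matches plotting "median gene
expression of all genes" as a per-gene quantity. Pooling all gene x sample
values before the median is a defensible alternative reading and is
available via `cohort_deregulation(..., aggregation="pooled")`; the default
is the per-gene-median form.

Two significance measures accompany the statistic:

- **Rank-sum p.** A two-sided Wilcoxon rank-sum test between set-member
  and non-member per-gene medians. A rank-based test is the
  assumption-light standard for a median comparison. Exact enumeration is
  used for small untied samples (both groups < 20), otherwise the normal
  approximation with midranks and continuity correction.
- **Permutation p.** M random gene sets of the same size are drawn without
  replacement and the statistic recomputed; the empirical p is the add-one
  estimator (1 + #{null >= observed}) / (M + 1), so p is never 0 and its
  floor is 1/(M+1). Ties count against significance (">=", conservative).
  M defaults to 10^4, giving a p floor of about 10^-4.

Cohorts are ranked by log2FC (rank 1 = largest), ties broken by smaller
rank-sum p, then lexicographic label. The 25/50/75% quantile reference for
per-gene medians uses linear interpolation between order statistics
(type-7), stated explicitly because quantile dialects differ.

Matched tumor/normal sub-cohorts are compared per gene with a two-sided
Wilcoxon signed-rank test: zero differences dropped, midranks for tied
absolute differences, exact enumeration of all 2^n sign assignments for
n <= 12 non-zero pairs (the exact path works under ties, which off-the-shelf
exact implementations refuse), and a tie-corrected normal approximation
above.

## Survival

Patients are stratified by one gene's expression into the top (>= 75th
percentile) and bottom (<= 25th percentile) quartiles; boundary ties join
the extreme group (inclusive cut) and the middle half is discarded.
Survival per stratum is the Kaplan-Meier product-limit estimate; the
strata are compared with the standard two-group log-rank test (chi-square,
1 df, two-sided, no continuity correction). Estimation is delegated to
lifelines; the package's tests verify the product-limit identity
S = prod(1 - d_i/n_i) stepwise and check the chi-square statistic against
a hand computation on a 6-event table. No Cox model is fit: the analysis
reports stratified curves and a two-group test only.

Calibration note: with 20 patients per stratum the chi-square reference is
visibly unstable (measured null rejection ~0.058 at alpha = 0.05); at the
default simulated cohort size of 500 (125 per stratum, the scale of the
motivating HNSCC cohort) the test is nominal. Calibration studies in the
test suite therefore run at the default cohort size.

## Differential expression

Per-gene testing uses a moderated pooled-variance t-statistic. With arm
sizes n1, n2 and pooled variance s_g^2 on d = n1 + n2 - 2 df, each gene's
variance is shrunk toward the genome-wide median pooled variance s_0^2
with a fixed prior weight d0:

    s_mod^2 = (d0 s_0^2 + d s_g^2) / (d0 + d),
    t_g = (mean_treated - mean_control) / sqrt(s_mod^2 (1/n1 + 1/n2)),

referred to t with d0 + d df. Rationale: at triplicates a raw per-gene
variance has 4 df and is far too noisy — a plain Welch test recovers only
~76% of genes carrying a -2 log2 shift at noise 0.25 under the study's
thresholds, versus ~100% with moderation — and borrowing strength across
genes is the standard remedy. d0 = 4 (equal weight to data at triplicates)
is fixed rather than estimated; the full empirical-Bayes treatment is a
deliberate non-goal, and DE lists from moderated pipelines will differ in
detail. The shrinkage also keeps degenerate zero-variance genes testable;
genes with no variance anywhere and no mean difference get p = 1.

Calls use the study thresholds exactly: Benjamini-Hochberg adjusted
p < 0.05 (statsmodels step-up) combined with log2FC > 1 ("up") or < -1
("down"). Venn-region counts over per-condition significant lists are exact
set algebra; regions are pairwise disjoint and partition the union.
Over-representation is the upper-tail hypergeometric test per flat gene
set, Bonferroni-corrected by the number of sets with non-empty universe
overlap (not the full collection). The universe defaults to all genes on
the matrix.

## Bench quantification

- **Dose-response.** Viability (% of control) is fit with the
  four-parameter logistic `bottom + (top - bottom)/(1 + (dose/ec50)^h)`
  by bounded least squares (initialisation: bottom = min response, top =
  max response, ec50 = dose nearest mid-response, h = 1). A flat or
  non-identifiable curve returns a non-convergence flag, never silent
  parameters. IC-x is the dose where the fitted curve crosses the absolute
  (100 - x)% of control level (the MTT reporting convention; the
  relative-asymptote definition is available via a flag), found by Brent's
  method on a bracket extending the observed dose range tenfold.
- **Bootstrap CIs.** Case-resampling bootstrap over (dose, response)
  pairs, B = 1000 default (floor 200; >= 300 recommended for stable tail
  quantiles). Intervals are BCa by default — bias correction from the
  bootstrap distribution, acceleration from a leave-one-out jackknife —
  because with ~20 observations the raw percentile interval of a
  nonlinear-regression parameter measurably undercovers. In this
  package's simulations (7 doses x 3 wells, noise 2% of control) the
  EC50 interval's true coverage at nominal 95% is ~0.90 for percentile
  and ~0.92-0.93 for BCa; residual and stratified-by-dose resampling do
  no better. Mild undercoverage is intrinsic to bootstrap intervals for
  nonlinear least squares at this sample size — treat the reported 95%
  intervals as approximate, or enlarge the design when calibrated
  intervals matter. `method="percentile"` gives the uncorrected
  interval. A resample that
  fails to fit counts as a failure; more than 20% failures withholds the
  intervals. An IC level unattainable on one resample blanks that IC only.
- **qPCR.** 2^-ddCt with dCt = Ct(target) - Ct(reference) per replicate
  and ddCt = mean dCt(treated) - mean dCt(control); per-replicate folds
  are also returned for spread. The fold is invariant to adding a constant
  to both target and reference Cts.
- **Densitometry** divides each band by its loading control and normalises
  to the untreated lane (control = 1); invariant to rescaling all four
  intensities.
- **Colony assays** report 100 x mean(treated)/mean(control) over >= 3
  replicate wells with a pooled-variance Student t p.
- **Phase fractions** report fold = treated/control for a named phase,
  rounded to one decimal (e.g. G2/M 52% vs 14% -> 3.7). Fractions must sum
  to 95-105% (slack for debris/gating loss).
- **Tumor metrics.** Volume = a x b^2 x 0.5 with a the longer caliper
  diameter (inputs reordered); area = a x b by default, pi/4 x a x b via
  flag since the source convention is unstated.

## Synthetic data

The generators produce data with exactly the structure the analyses
assume, plus the ground truth used by recovery tests:

- **Pan-cancer expression**: gene x sample log2 values i.i.d.
  Normal(baseline_mean, baseline_sd), with a per-cohort delta added to the
  designated set's genes. Defaults: 24 cohorts, 2000 genes, 100
  samples/cohort, 200-gene set, baseline 8 +/- 2 log2 units. A log2-normal
  model is sufficient because every downstream statistic is median- or
  rank-based; the exact law is not load-bearing.
- **Survival**: exponential event times with hazard
  baseline_hazard x exp(beta x covariate), independent uniform censoring
  on (0, max_follow_up) for a configurable fraction plus administrative
  censoring at max_follow_up. Defaults: 500 patients, baseline hazard
  1/1000 per day, 30% censoring, 3000-day follow-up.
- **Treatment arrays**: a shared per-gene baseline, i.i.d. Normal(0,
  noise_sd) replicate noise, and a monotone non-increasing log2 shift on
  the target set across conditions (control, IC25, IC50, IC75; defaults
  0/-0.5/-1/-2, noise 0.25, triplicates — the treated/control microarray
  design at its published scale of 3 treated conditions x 3 replicates
  + 3 controls).
- **Viability curves**: 4PL plus Gaussian noise, triplicate wells per dose.
- **qPCR**: treated target Ct = control Ct - log2(fold) + noise; reference
  Ct constant up to the same noise.

What the generators do *not* emulate: gene-gene correlation, per-gene
baseline heterogeneity, batch and platform effects, non-proportional
hazards, or informative censoring. Passing recovery tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not robustness to real-data pathologies.

All generators are pure functions of (config, seed) using numpy's PCG64;
a master seed expands into per-stage child seeds by drawing 31-bit
integers in a fixed stage order (`synthetic_data.child_seeds`), so each
stage is independently reproducible and full pipeline reruns are
byte-identical.

## Problem sizes in the test suite

Monte-Carlo studies in the suite use sizes chosen to make their acceptance
bands statistically meaningful at desk scale: 50-seed recovery of a unit
log2 shift (2000 genes, 200-gene set, 100 samples); 200-replicate null
calibrations for the permutation p (M = 400 per replicate, enough to
resolve alpha = 0.05) and the quartile log-rank (500 patients per
replicate); 200-replicate EC50 coverage at B = 300 bootstrap resamples;
20-seed DE sensitivity at 1000 genes. Exhaustive oracles (permutation
labelings, sign assignments, hypergeometric draws) run on instances small
enough to enumerate completely.

## Known limitations

- The DE test is a fixed-weight moderation, not full empirical Bayes;
  with strongly heteroscedastic real arrays the fixed d0 = 4 overweights
  the common variance.
- The log-rank p is asymptotic; below ~30 subjects per stratum prefer a
  permutation version (not implemented).
- The 4PL fitter assumes a monotone response; biphasic curves will fit
  poorly and should be caught via the residual SSE and convergence flag.
- Gene identifiers are matched case-sensitively with no alias resolution;
  the gene set is whatever the user supplies.
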